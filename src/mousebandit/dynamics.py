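"""Action-dynamics measures computed from one aligned cursor path.

Thirty per-path measures covering extreme positions, deviation from the
straight start-to-end segment, directional changes, timing and pausing,
distance and kinematics, and sample entropy as a path-complexity index.
Deviations are signed so that positive values point toward the non-chosen
option's side of the direct path ("above"), keeping coefficients
interpretable as distractor attraction.  Times are in seconds relative to
the path's first sample; positions in aligned pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class DynamicsConfig:
    hover_threshold_ms: float = 250.0
    flip_threshold_px: float = 0.0
    initiation_threshold_px: float = 0.0
    velocity_eps_px: float = 0.0  # displacement at or below this counts as "no movement"
    signed_auc: bool = True  # net signed area; False: absolute area
    entropy_m: int = 3
    entropy_r_factor: float = 0.2


FEATURE_COLUMNS = [
    "max_x",
    "min_x",
    "max_y",
    "min_y",
    "mad_signed",
    "mad_abs",
    "mad_time",
    "md_above",
    "md_below",
    "md_above_time",
    "md_below_time",
    "ad",
    "auc",
    "flips_x",
    "flips_y",
    "reversals_x",
    "reversals_y",
    "rt",
    "initiation_time",
    "idle_time",
    "hover_time",
    "n_hovers",
    "total_distance",
    "max_velocity",
    "max_velocity_time",
    "max_acceleration",
    "max_acceleration_time",
    "min_acceleration",
    "min_acceleration_time",
    "entropy",
]


def signed_deviations(samples: np.ndarray) -> np.ndarray:
    """Perpendicular signed distance of each sample from the start-end segment.

    Positive = the side of the non-chosen option (x > direct path in
    mirrored/aligned space).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    p = samples[:, 1:3] - samples[0, 1:3]
    d = p[-1]
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("zero net displacement")
    u = d / nrm
    # cross product z-component; negated so the distractor side is positive
    return -(u[0] * p[:, 1] - u[1] * p[:, 0])


def deviation_measures(samples: np.ndarray, config: DynamicsConfig = DynamicsConfig()) -> dict:
    dev = signed_deviations(samples)
    t = (samples[:, 0] - samples[0, 0]) / 1000.0
    p = samples[:, 1:3] - samples[0, 1:3]
    u = p[-1] / np.linalg.norm(p[-1])
    proj = p @ u  # arc progression along the direct axis
    i_mad = int(np.argmax(np.abs(dev)))
    i_above = int(np.argmax(dev))
    i_below = int(np.argmin(dev))
    auc = float(np.trapezoid(dev, proj))
    if not config.signed_auc:
        auc = float(np.trapezoid(np.abs(dev), proj))
    return {
        "mad_signed": float(dev[i_mad]),
        "mad_abs": float(abs(dev[i_mad])),
        "mad_time": float(t[i_mad]),
        "md_above": float(dev[i_above]),
        "md_below": float(dev[i_below]),
        "md_above_time": float(t[i_above]),
        "md_below_time": float(t[i_below]),
        "ad": float(dev.mean()),
        "auc": auc,
    }


def _count_flips(vals: np.ndarray, threshold: float) -> int:
    """Directional changes along one axis.

    A flip is counted when the coordinate moves against the current
    direction by more than ``threshold`` from the running extremum; with the
    default threshold 0 this is the number of sign changes of the nonzero
    increments.
    """
    direction = 0
    ref = vals[0]
    flips = 0
    for v in vals[1:]:
        if direction == 0:
            if abs(v - ref) > threshold:
                direction = 1 if v > ref else -1
                ref = v
        elif (v - ref) * direction > 0:
            ref = v
        elif abs(v - ref) > threshold:
            flips += 1
            direction = -direction
            ref = v
    return flips


def _count_reversals(vals: np.ndarray) -> int:
    """Transversal crossings of the zero line after having left it."""
    signs = np.sign(vals)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def directional_changes(samples: np.ndarray, config: DynamicsConfig = DynamicsConfig()) -> dict:
    x, y = samples[:, 1], samples[:, 2]
    th = config.flip_threshold_px
    return {
        "flips_x": _count_flips(x, th),
        "flips_y": _count_flips(y, th),
        "reversals_x": _count_reversals(x - x[0]),
        "reversals_y": _count_reversals(y - y[0]),
    }


def timing_measures(samples: np.ndarray, config: DynamicsConfig = DynamicsConfig()) -> dict:
    t = samples[:, 0]
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be non-decreasing")
    rel = (t - t[0]) / 1000.0
    rt = float(rel[-1])
    disp_from_start = np.linalg.norm(samples[:, 1:3] - samples[0, 1:3], axis=1)
    moved = np.flatnonzero(disp_from_start > config.initiation_threshold_px)
    initiation = float(rel[moved[0]]) if len(moved) else rt
    step = np.linalg.norm(np.diff(samples[:, 1:3], axis=0), axis=1)
    dt = np.diff(rel)
    idle = step <= config.velocity_eps_px
    idle_time = float(dt[idle].sum())
    # hovers: maximal idle runs of duration >= threshold
    hover_time = 0.0
    n_hovers = 0
    run = 0.0
    thr = config.hover_threshold_ms / 1000.0
    for i, is_idle in enumerate(idle):
        if is_idle:
            run += dt[i]
        else:
            if run >= thr and run > 0:
                n_hovers += 1
                hover_time += run
            run = 0.0
    if run >= thr and run > 0:
        n_hovers += 1
        hover_time += run
    return {
        "rt": rt,
        "initiation_time": initiation,
        "idle_time": idle_time,
        "hover_time": hover_time,
        "n_hovers": n_hovers,
    }


def kinematics(samples: np.ndarray) -> dict:
    """Distance, velocity and acceleration extrema with their timepoints.

    Velocities live at interval midpoints; accelerations at the interior
    sample shared by consecutive intervals.  Duplicate timestamps are merged
    first.  Acceleration is missing (NaN) with fewer than 3 distinct-time
    samples.
    """
    t = samples[:, 0] / 1000.0
    keep = np.concatenate([[True], np.diff(t) > 0])
    s = samples[keep]
    t = s[:, 0] / 1000.0
    out = {
        "total_distance": float(
            np.linalg.norm(np.diff(samples[:, 1:3], axis=0), axis=1).sum()
        ),
        "max_velocity": np.nan,
        "max_velocity_time": np.nan,
        "max_acceleration": np.nan,
        "max_acceleration_time": np.nan,
        "min_acceleration": np.nan,
        "min_acceleration_time": np.nan,
    }
    if len(s) < 2:
        return out
    step = np.linalg.norm(np.diff(s[:, 1:3], axis=0), axis=1)
    dt = np.diff(t)
    v = step / dt
    mid = (t[:-1] + t[1:]) / 2.0
    iv = int(np.argmax(v))
    out["max_velocity"] = float(v[iv])
    out["max_velocity_time"] = float(mid[iv] - t[0])
    if len(s) >= 3:
        a = np.diff(v) / np.diff(mid)
        ta = t[1:-1] - t[0]
        ia, ja = int(np.argmax(a)), int(np.argmin(a))
        out["max_acceleration"] = float(a[ia])
        out["max_acceleration_time"] = float(ta[ia])
        out["min_acceleration"] = float(a[ja])
        out["min_acceleration_time"] = float(ta[ja])
    return out


def sample_entropy(
    series: np.ndarray, m: int = 3, r_factor: float = 0.2
) -> float:
    """Sample entropy -ln(A/B) of a series under Chebyshev tolerance r.

    ``r = r_factor * SD(series)``; B counts matching template pairs of
    length m (over the indices that admit an (m+1)-extension), A the pairs
    still matching at length m+1.  Perfectly regular series give 0; returns
    NaN when the series is too short or no template pair matches.
    """
    u = np.asarray(series, float)
    n = len(u)
    if n < m + 2:
        return np.nan
    r = r_factor * u.std()
    win_m = sliding_window_view(u, m)[: n - m]  # only templates extendable to m+1
    win_m1 = sliding_window_view(u, m + 1)
    iu = np.triu_indices(n - m, k=1)
    d_m = np.abs(win_m[:, None, :] - win_m[None, :, :]).max(axis=-1)[iu]
    d_m1 = np.abs(win_m1[:, None, :] - win_m1[None, :, :]).max(axis=-1)[iu]
    B = int(np.count_nonzero(d_m <= r))
    A = int(np.count_nonzero(d_m1 <= r))
    if B == 0 or A == 0:
        return np.nan
    return float(-np.log(A / B))


def path_entropy(samples: np.ndarray, config: DynamicsConfig = DynamicsConfig()) -> float:
    """Sample entropy of the first-differenced x-coordinate series."""
    return sample_entropy(np.diff(samples[:, 1]), config.entropy_m, config.entropy_r_factor)


def compute_dynamics(samples: np.ndarray, config: DynamicsConfig = DynamicsConfig()) -> dict:
    """The full measure battery for one aligned path (n, 3) array."""
    x, y = samples[:, 1], samples[:, 2]
    out = {
        "max_x": float(x.max()),
        "min_x": float(x.min()),
        "max_y": float(y.max()),
        "min_y": float(y.min()),
    }
    out.update(deviation_measures(samples, config))
    out.update(directional_changes(samples, config))
    out.update(timing_measures(samples, config))
    out.update(kinematics(samples))
    out["entropy"] = path_entropy(samples, config)
    return out


def compute_features_table(
    aligned: pd.DataFrame, config: DynamicsConfig = DynamicsConfig()
) -> pd.DataFrame:
    """One row of measures per (participant, trial, phase) from aligned samples."""
    rows = []
    for (participant, trial, phase), g in aligned.groupby(
        ["participant", "trial", "phase"], sort=True
    ):
        g = g.sort_values("t_ms")
        samples = g[["t_ms", "x", "y"]].to_numpy(float)
        row = {"participant": participant, "trial": trial, "phase": phase}
        if len(samples) < 2:
            row.update({c: np.nan for c in FEATURE_COLUMNS})
        else:
            row.update(compute_dynamics(samples, config))
        rows.append(row)
    return pd.DataFrame(rows)
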