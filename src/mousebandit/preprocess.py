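"""Mouse-path preprocessing: exclusion, mirroring, splitting, alignment.

The pipeline order is: (1) exclude trials whose recorded start deviates more
than 20 px from the expected start position on either axis; (2) mirror
right-choice paths about the vertical axis through the start so every path
leads to a target on the left; (3) split each trial's samples into the
decision path (start until the cursor first reaches the chosen option's
edge) and the post-decision/return path (from there until the cursor first
re-enters the start circle); (4) align each path affinely so it starts at
(0, 0) and ends at (-250, 350), with y increasing upward toward the targets.
All action-dynamics measures are computed in this aligned space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALIGN_TARGET = (-250.0, 350.0)
START_DEVIATION_THRESHOLD_PX = 20.0


class MalformedTrialError(ValueError):
    """A trial's samples never reach the required region boundary."""


class AlignmentError(ValueError):
    """A path cannot be aligned (zero net displacement along an axis)."""


@dataclass
class AlignedPath:
    """One aligned movement path.

    ``samples`` is (n, 3): t_ms, x, y in aligned coordinates (start (0,0),
    end (-250, 350), y up).  ``excluded``/``reason`` record the exclusion
    filter's verdict; excluded paths carry their raw samples unchanged.
    """

    phase: str
    samples: np.ndarray
    excluded: bool = False
    reason: str | None = None
    mirrored: bool = False
    degenerate: bool = False


def exclude_bad_starts(
    paths: list[np.ndarray],
    expected_start: tuple[float, float],
    threshold_px: float = START_DEVIATION_THRESHOLD_PX,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Partition path indices into retained and (index, reason) excluded.

    A path is excluded iff |dx| > threshold or |dy| > threshold at its first
    sample; a deviation of exactly the threshold is retained.
    """
    retained, excluded = [], []
    ex, ey = expected_start
    for i, path in enumerate(paths):
        if len(path) == 0:
            excluded.append((i, "empty"))
            continue
        dx = abs(path[0, 1] - ex)
        dy = abs(path[0, 2] - ey)
        if dx > threshold_px or dy > threshold_px:
            excluded.append((i, f"start deviation ({dx:.0f}, {dy:.0f}) px"))
        else:
            retained.append(i)
    return retained, excluded


def mirror_right_choices(samples: np.ndarray, choice_side: str, axis_x: float) -> np.ndarray:
    """Reflect right-choice paths about the vertical line x = axis_x."""
    if choice_side == "left":
        return samples
    out = samples.copy()
    out[:, 1] = 2.0 * axis_x - out[:, 1]
    return out


def split_decision_return(
    samples: np.ndarray,
    chosen_center: tuple[float, float],
    chosen_radius: float,
    start_center: tuple[float, float],
    start_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split full-trial samples at the choice and the return to start.

    The decision path runs from the first sample to the first sample at or
    inside the chosen option's edge; the return path continues from that
    sample until the first subsequent sample at or inside the start circle's
    edge.
    """
    xy = samples[:, 1:3]
    d_choice = np.linalg.norm(xy - np.asarray(chosen_center), axis=1)
    inside = np.flatnonzero(d_choice <= chosen_radius)
    if len(inside) == 0:
        raise MalformedTrialError("path never reaches the chosen option's edge")
    k = int(inside[0])
    d_start = np.linalg.norm(xy[k:] - np.asarray(start_center), axis=1)
    back = np.flatnonzero(d_start <= start_radius)
    if len(back) == 0:
        raise MalformedTrialError("return path never re-enters the start circle")
    m = k + int(back[0])
    return samples[: k + 1].copy(), samples[k : m + 1].copy()


def align(samples: np.ndarray, phase: str = "decision") -> AlignedPath:
    """Translate and axis-rescale a path to the canonical endpoints.

    The first sample maps to (0, 0) and the last to (-250, 350); each axis
    is scaled independently (the minimal affine map forcing the endpoints),
    which also converts screen y-down coordinates to y-up.  Timestamps are
    unchanged.
    """
    if len(samples) == 0:
        raise ValueError("empty path")
    out = samples.astype(float).copy()
    out[:, 1] -= samples[0, 1]
    out[:, 2] -= samples[0, 2]
    dx, dy = out[-1, 1], out[-1, 2]
    if dx == 0 or dy == 0:
        raise AlignmentError("zero net displacement along an axis")
    out[:, 1] *= ALIGN_TARGET[0] / dx
    out[:, 2] *= ALIGN_TARGET[1] / dy
    degenerate = len(samples) == 1
    return AlignedPath(phase=phase, samples=out, mirrored=False, degenerate=degenerate)


def preprocess_dataset(
    tracking: pd.DataFrame,
    trajectory_config,
    threshold_px: float = START_DEVIATION_THRESHOLD_PX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full preprocessing pipeline on a raw tracking log.

    Returns ``(aligned, exclusions)``: a long-format table of aligned path
    samples (participant, trial, phase, t_ms, x, y) and an exclusions report
    (participant, trial, reason).  ``trajectory_config`` provides the screen
    geometry (start/target circle centers and radii).
    """
    cfg = trajectory_config
    start_center = np.array(cfg.start_xy, float)
    aligned_parts = []
    exclusions = []
    for (participant, trial), g in tracking.groupby(["participant", "trial"], sort=True):
        g = g.sort_values("t_ms")
        samples = g[["t_ms", "x_px", "y_px"]].to_numpy(float)
        # merge duplicate timestamps across phase boundaries
        keep = np.concatenate([[True], np.diff(samples[:, 0]) > 0])
        samples = samples[keep]
        meta = g.iloc[0]
        # 1) exclusion on start deviation
        dx = abs(samples[0, 1] - start_center[0])
        dy = abs(samples[0, 2] - start_center[1])
        if len(samples) == 0 or dx > threshold_px or dy > threshold_px:
            exclusions.append(
                {
                    "participant": participant,
                    "trial": trial,
                    "reason": f"start deviation ({dx:.0f}, {dy:.0f}) px",
                }
            )
            continue
        # 2) mirroring
        side = meta["choice_side"]
        samples = mirror_right_choices(samples, side, start_center[0])
        chosen_center = np.array(cfg.target_xy("left"), float)  # all paths lead left now
        # 3) splitting
        try:
            dec, ret = split_decision_return(
                samples, chosen_center, cfg.target_radius, start_center, cfg.start_radius
            )
        except MalformedTrialError as err:
            exclusions.append({"participant": participant, "trial": trial, "reason": str(err)})
            continue
        # 4) alignment
        for phase, part in (("decision", dec), ("return", ret)):
            try:
                ap = align(part, phase)
            except AlignmentError as err:
                exclusions.append(
                    {"participant": participant, "trial": trial, "reason": f"{phase}: {err}"}
                )
                continue
            df = pd.DataFrame(ap.samples, columns=["t_ms", "x", "y"])
            df.insert(0, "phase", phase)
            df.insert(0, "trial", trial)
            df.insert(0, "participant", participant)
            for col in ("block", "trial_type"):
                if col in g.columns:
                    df[col] = meta[col]
            aligned_parts.append(df)
    aligned = (
        pd.concat(aligned_parts, ignore_index=True)
        if aligned_parts
        else pd.DataFrame(columns=["participant", "trial", "phase", "t_ms", "x", "y"])
    )
    report = pd.DataFrame(exclusions, columns=["participant", "trial", "reason"])
    return aligned, report
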