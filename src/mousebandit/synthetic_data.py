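"""Synthetic agents and synthetic cursor trajectories.

Two generators live here.  :func:`simulate_agent` plays the Bayesian learner
on a fresh task schedule, choosing by softmax on its own expected values, and
returns the trial log.  :func:`generate_trajectory` produces a cursor path
for one movement (decision or post-decision return) whose spatiotemporal
features covary with the trial's latent variables: a minimum-jerk baseline
from start to target, a mid-movement lateral pull toward the distractor
whose amplitude shrinks with confidence and context (decision) or drifts
with the signed prediction error (return), pauses ("hovers") inserted with
probability increasing in uncertainty and surprise, and a small fraction of
"deviant" paths that loop toward the non-chosen option — emulating the two
empirical movement phenotypes (direct vs distractor-deviating with hovers).

The trajectory generator is a fixture generator with a controllable
latent-to-feature coupling, not a cognitive model of motor control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_model import (
    DEFAULT_GRID_SIZE,
    ModelParams,
    extract_latents,
    likelihood_density,
    trapezoid_weights,
)
from .task_env import (
    OPTIONS,
    TaskConfig,
    draw_outcome,
    generate_schedule,
    schedule_frame,
)

TRACKING_COLUMNS = [
    "participant",
    "block",
    "trial",
    "trial_type",
    "phase",
    "choice_side",
    "t_ms",
    "x_px",
    "y_px",
]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Geometry and latent-coupling coefficients of the trajectory generator.

    Geometry emulates the task screen (1536 x 864 px, y increasing downward):
    start circle bottom-center, choice options top-left and top-right.
    Effect coefficients are free parameters of the generator; defaults are
    chosen to give a clear qualitative separation between direct and deviant
    paths and monotone latent-feature couplings.
    """

    sample_rate: float = 100.0  # Hz
    screen: tuple[int, int] = (1536, 864)
    start_xy: tuple[float, float] = (768.0, 780.0)
    start_radius: float = 40.0
    target_left_xy: tuple[float, float] = (368.0, 200.0)
    target_right_xy: tuple[float, float] = (1168.0, 200.0)
    target_radius: float = 50.0
    noise_sd: float = 1.0  # px, Gaussian positional noise
    start_jitter: float = 5.0  # px, uniform per-axis start jitter
    # response-time couplings (multiplicative, per unit of the latent)
    base_rt_decision: float = 0.75  # s
    base_rt_return: float = 0.55  # s
    beta_conf_rt: float = 0.6  # RT lengthening with (1 - confidence)
    beta_context_rt: float = 0.35  # RT lengthening with (0.5 - context)
    beta_abspe_rt: float = 0.5  # RT lengthening with |PE| (return phase)
    # lateral-deviation couplings (px)
    beta_conf_mad: float = 120.0  # pull amplitude per unit (1 - confidence)
    beta_context_mad: float = 40.0  # pull amplitude per unit (0.5 - context)
    lateral_noise_sd: float = 10.0  # trial-to-trial symmetric pull variation (px)
    beta_pe_drift: float = 60.0  # return drift per unit signed PE
    deviant_amplitude: float = 260.0  # extra pull on deviant paths
    # hover couplings
    beta_conf_hover: float = 0.5  # hover probability per unit (1 - confidence)
    beta_abspe_hover: float = 0.5  # hover probability per unit |PE|
    hover_base_prob: float = 0.03
    hover_dur_range: tuple[float, float] = (280.0, 700.0)  # ms
    # deviant-path phenotype
    p_deviant_base: float = 0.11
    deviant_conf_slope: float = 4.0
    deviant_conf_ref: float = 0.65  # typical mean confidence of simulated agents
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        w, h = self.screen
        for name in ("start_xy", "target_left_xy", "target_right_xy"):
            x, y = getattr(self, name)
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(f"{name} lies outside the screen")

    def target_xy(self, side: str) -> tuple[float, float]:
        return self.target_left_xy if side == "left" else self.target_right_xy


def simulate_agent(
    config: TaskConfig,
    params: ModelParams,
    rng: np.random.Generator,
    K: int = DEFAULT_GRID_SIZE,
) -> pd.DataFrame:
    """Play the Bayesian learner through one session; return the trial log.

    The agent chooses by softmax on its current expected values on every
    trial (learning trials included), observes the sampled outcome, and
    updates beliefs.  Beliefs reset to uniform at each block start.
    """
    designs = generate_schedule(config, rng)
    grid = np.linspace(0.0, 1.0, K)
    w = trapezoid_weights(grid)
    gw = grid * w
    L = {o: likelihood_density(o, grid) for o in (1, -1, 0)}
    g, T = params.gamma, params.temperature
    dens = np.ones((2, K))
    prev_block = None
    points = config.start_points
    choices, sides, outcomes, counted, points_after = [], [], [], [], []
    for design in designs:
        if design.block != prev_block:
            dens = np.ones((2, K))
            prev_block = design.block
        sign = 1.0 if design.block == "gain" else -1.0
        means = sign * (dens @ gw)
        z = (means - means.max()) / T
        p_red = float(np.exp(z[0]) / (np.exp(z[0]) + np.exp(z[1])))
        ci = 0 if rng.random() < p_red else 1
        choice = OPTIONS[ci]
        rec = draw_outcome(design, choice, config, rng, points)
        points = rec.points_after
        choices.append(choice)
        sides.append(design.option_positions[choice])
        outcomes.append(rec.outcome)
        counted.append(rec.counted)
        points_after.append(points)
        post_c = g * dens[ci] * L[rec.outcome] + (1.0 - g)
        post_o = g * dens[1 - ci] + (1.0 - g)
        dens[ci] = post_c / (w @ post_c)
        dens[1 - ci] = post_o / (w @ post_o)
    df = schedule_frame(designs)
    df["choice"] = choices
    df["choice_side"] = sides
    df["outcome"] = outcomes
    df["counted"] = counted
    df["points_after"] = points_after
    return df


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_trajectory(
    latents: dict,
    phase: str,
    config: TrajectoryConfig,
    rng: np.random.Generator,
    t0_ms: float = 0.0,
    start_offset: tuple[float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Generate one cursor path; returns (samples, info).

    ``samples`` is an (n, 3) array of (t_ms, x_px, y_px) with integer pixel
    coordinates.  ``latents`` must contain ``choice_side`` plus, for the
    decision phase, ``confidence`` and ``context``; for the return phase,
    ``pe`` and ``abs_pe``.  ``info`` reports the drawn phenotype and hover
    bookkeeping.  ``start_offset`` overrides the uniform start jitter (used
    to inject exclusion-filter outliers).
    """
    side = latents["choice_side"]
    target = np.array(config.target_xy(side), float)
    other = np.array(config.target_xy("left" if side == "right" else "right"), float)
    start_center = np.array(config.start_xy, float)
    if start_offset is None:
        start_offset = rng.uniform(-config.start_jitter, config.start_jitter, size=2)
    deviant = False
    if phase == "decision":
        for key in ("confidence", "context"):
            if key not in latents:
                raise ValueError(f"latent {key!r} required for decision phase")
        conf = float(latents["confidence"])
        ctx = float(latents["context"])
        p0 = start_center + np.asarray(start_offset, float)
        p1 = target + (config.target_radius * 0.8) * _unit(p0 - target)
        duration = config.base_rt_decision * (
            1.0
            + config.beta_conf_rt * (1.0 - conf)
            + config.beta_context_rt * (0.5 - ctx)
        )
        p_dev = _sigmoid(
            np.log(config.p_deviant_base / (1 - config.p_deviant_base))
            + config.deviant_conf_slope * (config.deviant_conf_ref - conf)
        )
        deviant = bool(rng.random() < p_dev)
        amp = config.beta_conf_mad * (1.0 - conf) + config.beta_context_mad * (0.5 - ctx)
        amp += rng.normal(0.0, config.lateral_noise_sd)
        if deviant:
            amp += config.deviant_amplitude
        p_hover = config.hover_base_prob + config.beta_conf_hover * (1.0 - conf)
        if deviant:
            p_hover = max(p_hover, 0.9)
        toward = other
    elif phase == "return":
        for key in ("pe", "abs_pe"):
            if key not in latents:
                raise ValueError(f"latent {key!r} required for return phase")
        pe = float(latents["pe"])
        abs_pe = float(latents["abs_pe"])
        p0 = target + (config.target_radius * 0.8) * _unit(start_center - target)
        p1 = start_center + np.asarray(start_offset, float)
        duration = config.base_rt_return * (1.0 + config.beta_abspe_rt * abs_pe)
        # positive PE drifts away from the distractor side
        amp = -config.beta_pe_drift * pe + rng.normal(0.0, config.lateral_noise_sd)
        p_hover = config.hover_base_prob + config.beta_abspe_hover * abs_pe
        toward = other
    else:
        raise ValueError(f"unknown phase {phase!r}")

    duration = max(duration, 0.25)
    n = max(int(round(duration * config.sample_rate)) + 1, 5)
    tau = np.linspace(0.0, 1.0, n)
    s = _minimum_jerk(tau)
    path = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    # lateral component: perpendicular to the straight line, signed toward
    # the non-chosen option, peaking mid-movement
    d = _unit(p1 - p0)
    perp = np.array([-d[1], d[0]])
    mid = (p0 + p1) / 2
    if np.dot(perp, toward - mid) < 0:
        perp = -perp
    path += (amp * np.sin(np.pi * tau) ** 2)[:, None] * perp[None, :]
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n, 2))
        noise[0] = 0.0
        path += noise
        path = np.rint(path)  # integer pixel log, as a real recording would be

    dt = 1000.0 / config.sample_rate
    t = t0_ms + dt * np.arange(n)
    samples = np.column_stack([t, path])
    # hovers: zero-velocity plateaus of duration drawn from hover_dur_range
    n_hovers = 0
    hover_ms = 0.0
    if rng.random() < min(p_hover, 0.95):
        n_hovers = 1 + int(rng.random() < 0.3)
    for _ in range(n_hovers):
        dur = rng.uniform(*config.hover_dur_range)
        k = max(int(round(dur / dt)), 1)
        at = int(rng.integers(1, n - 1))
        plateau = np.repeat(samples[at : at + 1], k, axis=0)
        samples = np.concatenate([samples[: at + 1], plateau, samples[at + 1 :]])
        hover_ms += k * dt
    samples[:, 0] = t0_ms + dt * np.arange(len(samples))
    info = {"deviant": deviant, "n_hovers_inserted": n_hovers, "hover_ms": hover_ms}
    return samples, info


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("zero-length direction")
    return v / nrm


def generate_dataset(
    n_participants: int = 115,
    task_config: TaskConfig | None = None,
    trajectory_config: TrajectoryConfig | None = None,
    param_sampler=None,
    seed: int = 0,
    trajectories_for: str = "all",
    n_start_outliers: int = 0,
    K: int = DEFAULT_GRID_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full study: agents, latents and cursor trajectories.

    Returns ``(trials, tracking)``: the per-trial table (design, behaviour,
    latents, generator truth) and the long-format raw tracking log with one
    row per cursor sample.  ``trajectories_for`` selects which trials get
    trajectories ("all" or "exploitation").  ``n_start_outliers`` trials are
    given a start offset larger than the 20-px exclusion threshold so the
    preprocessing filter is exercisable.

    ``param_sampler(rng) -> ModelParams`` draws each participant's true
    parameters; the default concentrates gamma near 1 and the temperature
    near 0.05-0.1, matching the regime the learner is meant to operate in.
    """
    task_config = task_config or TaskConfig()
    trajectory_config = trajectory_config or TrajectoryConfig()
    if param_sampler is None:

        def param_sampler(rng: np.random.Generator) -> ModelParams:
            gamma = 1.0 - 10 ** rng.uniform(-3.0, -0.7)
            temperature = 10 ** rng.uniform(np.log10(0.02), np.log10(0.3))
            return ModelParams(gamma, temperature)

    ss = np.random.SeedSequence(seed)
    trial_frames, tracking_parts = [], []
    participant_seeds = ss.spawn(n_participants + 1)
    outlier_rng = np.random.default_rng(participant_seeds[-1])
    for p in range(n_participants):
        rng = np.random.default_rng(participant_seeds[p])
        params = param_sampler(rng)
        trials = simulate_agent(task_config, params, rng, K=K)
        # recompute latents from the recorded choices/outcomes
        latents = extract_latents(
            _designs_from_frame(trials), list(trials["choice"]), list(trials["outcome"]), params, K=K
        )
        trials = trials.merge(
            latents.drop(columns=["block", "trial_in_block", "trial_type", "choice", "outcome"]),
            on="trial",
        )
        trials.insert(0, "participant", p + 1)
        trials["gamma_true"] = params.gamma
        trials["temperature_true"] = params.temperature
        mask = (
            np.ones(len(trials), bool)
            if trajectories_for == "all"
            else (trials["trial_type"] == "exploitation").to_numpy()
        )
        deviants = np.zeros(len(trials), bool)
        for i in np.flatnonzero(mask):
            row = trials.iloc[i]
            lat = {
                "choice_side": row["choice_side"],
                "confidence": row["confidence"],
                "context": row["context"],
                "pe": row["pe"],
                "abs_pe": row["abs_pe"],
            }
            dec, info = generate_trajectory(lat, "decision", trajectory_config, rng)
            deviants[i] = info["deviant"]
            ret, _ = generate_trajectory(
                lat, "return", trajectory_config, rng, t0_ms=dec[-1, 0] + 1000.0 / trajectory_config.sample_rate
            )
            for phase, samples in (("decision", dec), ("return", ret)):
                part = pd.DataFrame(samples, columns=["t_ms", "x_px", "y_px"])
                part.insert(0, "choice_side", row["choice_side"])
                part.insert(0, "phase", phase)
                part.insert(0, "trial_type", row["trial_type"])
                part.insert(0, "trial", row["trial"])
                part.insert(0, "block", row["block"])
                part.insert(0, "participant", p + 1)
                tracking_parts.append(part)
        trials["deviant_path"] = deviants
        trial_frames.append(trials)
    trials_df = pd.concat(trial_frames, ignore_index=True)
    tracking_df = pd.concat(tracking_parts, ignore_index=True)[TRACKING_COLUMNS]
    if n_start_outliers > 0:
        tracking_df = inject_start_outliers(tracking_df, n_start_outliers, outlier_rng)
    return trials_df, tracking_df


def inject_start_outliers(
    tracking: pd.DataFrame, n: int, rng: np.random.Generator, min_px: float = 25.0, max_px: float = 60.0
) -> pd.DataFrame:
    """Shift exactly ``n`` randomly chosen trials' paths by > 20 px.

    The whole trial (both phases) is translated, emulating a miscalibrated
    recording, so the start-deviation exclusion filter has known positives.
    """
    keys = tracking[["participant", "trial"]].drop_duplicates().to_numpy()
    if n > len(keys):
        raise ValueError("more outliers requested than trials available")
    picked = keys[rng.permutation(len(keys))[:n]]
    out = tracking.copy()
    for participant, trial in picked:
        axis = "x_px" if rng.random() < 0.5 else "y_px"
        shift = rng.uniform(min_px, max_px) * (1 if rng.random() < 0.5 else -1)
        sel = (out["participant"] == participant) & (out["trial"] == trial)
        out.loc[sel, axis] += np.rint(shift)
    return out


def _designs_from_frame(trials: pd.DataFrame):
    from .task_env import TrialDesign

    return [
        TrialDesign(
            block=r.block,
            trial_index=r.trial_in_block if hasattr(r, "trial_in_block") else r.trial_index,
            is_exploitation=bool(r.is_exploitation),
            good_option=r.good_option,
            position_red=r.position_red,
            switched=bool(r.switched),
        )
        for r in trials.itertuples()
    ]


def write_tracking(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_tracking(path) -> pd.DataFrame:
    return pd.read_csv(path)
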