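"""Reduced Bayesian reinforcement-learning model of two-choice learning.

The learner tracks, for each option i, a belief distribution Pr(theta_i) over
the probability theta in [0,1] that the option yields a point outcome (+1 in
the gain block, -1 in the loss block).  Beliefs live on a discretized grid
and start uniform at each block.  After each outcome the chosen option's
belief is updated with a beta-distributed likelihood,

    L = Beta(alpha=2, beta=1.1)   for a gain/loss outcome,
        Beta(alpha=1.1, beta=2)   for no outcome,

mixed with the uniform via the forgetting weight gamma:

    Pr(theta_chosen)'     ~ gamma * Pr(theta_chosen) * L + (1 - gamma) * U(0,1)
    Pr(theta_non_chosen)' ~ gamma * Pr(theta_non_chosen) + (1 - gamma) * U(0,1)

gamma weights how informative past outcomes are: gamma = 1 is full Bayesian
retention, gamma = 0 resets beliefs to uniform each trial, and intermediate
values let the learner track the task's switching reward probabilities.
Choices are modelled with a softmax over the options' expected values with
temperature T.  Six trial-level latents are extracted: confidence,
context value, posterior variance, prediction error, its absolute value,
and the post-outcome change in confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .task_env import ConfigurationError, OPTIONS, TaskConfig, TrialDesign

DEFAULT_GRID_SIZE = 201


@dataclass(frozen=True)
class LikelihoodSpec:
    """Shape parameters of the beta outcome likelihoods.

    Both densities vanish at theta = 0 and 1 and peak near 0.9 (point
    outcome) or 0.1 (no outcome).
    """

    alpha_gainloss: float = 2.0
    beta_gainloss: float = 1.1
    alpha_nothing: float = 1.1
    beta_nothing: float = 2.0


@dataclass(frozen=True)
class ModelParams:
    """Free parameters: forgetting weight gamma and softmax temperature."""

    gamma: float
    temperature: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ConfigurationError(f"gamma must lie in [0, 1], got {self.gamma!r}")
        if not (self.temperature > 0.0):
            raise ConfigurationError(f"temperature must be positive, got {self.temperature!r}")


@dataclass
class BeliefState:
    """Discretized belief densities over theta for both options.

    ``density`` has shape (2, K); rows follow :data:`~mousebandit.task_env.OPTIONS`
    order (red, blue).  Densities are normalized to integrate to 1 by the
    trapezoid rule.
    """

    grid: np.ndarray
    density: np.ndarray
    _weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._weights = trapezoid_weights(self.grid)

    def option_index(self, option: str) -> int:
        return OPTIONS.index(option)

    def integral(self, option: str) -> float:
        return float(self._weights @ self.density[self.option_index(option)])

    def mean(self, option: str) -> float:
        d = self.density[self.option_index(option)]
        return float(self._weights @ (self.grid * d))

    def variance(self, option: str) -> float:
        i = self.option_index(option)
        d = self.density[i]
        m = self._weights @ (self.grid * d)
        m2 = self._weights @ (self.grid**2 * d)
        return float(m2 - m**2)

    def copy(self) -> "BeliefState":
        return BeliefState(grid=self.grid, density=self.density.copy())


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights such that w @ f equals the trapezoid-rule integral."""
    w = np.empty_like(grid)
    dx = np.diff(grid)
    w[0] = dx[0] / 2
    w[-1] = dx[-1] / 2
    w[1:-1] = (dx[:-1] + dx[1:]) / 2
    return w


def init_beliefs(K: int = DEFAULT_GRID_SIZE) -> BeliefState:
    """Uniform beliefs for both options on a K-point grid over [0, 1]."""
    if K < 3:
        raise ConfigurationError(f"grid size must be >= 3, got {K}")
    grid = np.linspace(0.0, 1.0, K)
    return BeliefState(grid=grid, density=np.ones((2, K)))


def likelihood_density(
    outcome: int, grid: np.ndarray, spec: LikelihoodSpec = LikelihoodSpec()
) -> np.ndarray:
    """Beta likelihood density on the grid for a point outcome (+1/-1) or nothing (0)."""
    if outcome in (1, -1):
        return beta_dist.pdf(grid, spec.alpha_gainloss, spec.beta_gainloss)
    if outcome == 0:
        return beta_dist.pdf(grid, spec.alpha_nothing, spec.beta_nothing)
    raise ValueError(f"outcome must be +1, -1 or 0, got {outcome!r}")


def update_beliefs(
    state: BeliefState,
    chosen: str,
    outcome: int,
    params: ModelParams,
    spec: LikelihoodSpec = LikelihoodSpec(),
) -> BeliefState:
    """One trial's belief update (applied on every trial, exploitation and learning)."""
    for opt in OPTIONS:
        if abs(state.integral(opt) - 1.0) > 1e-6:
            raise ValueError(f"input belief for {opt!r} is not normalized")
    new = state.copy()
    w = new._weights
    ci = state.option_index(chosen)
    L = likelihood_density(outcome, state.grid, spec)
    g = params.gamma
    post = g * state.density[ci] * L + (1.0 - g)
    new.density[ci] = post / (w @ post)
    other = g * state.density[1 - ci] + (1.0 - g)
    new.density[1 - ci] = other / (w @ other)
    return new


def expected_value(state: BeliefState, option: str, block: str) -> float:
    """EV = integral of theta Pr(theta); negated in the loss block."""
    m = state.mean(option)
    return m if block == "gain" else -m


def choice_probability(ev_chosen: float, ev_other: float, temperature: float) -> float:
    """Softmax probability of the chosen option given the two expected values."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    a = ev_chosen / temperature
    b = ev_other / temperature
    m = max(a, b)
    ea, eb = np.exp(a - m), np.exp(b - m)
    return float(ea / (ea + eb))


def confidence(state: BeliefState, chosen: str, other: str, block: str = "gain") -> float:
    """Probability that the chosen option is better than the non-chosen.

    In the gain block this is P(theta_chosen > theta_other) under the two
    independent belief densities; in the loss block theta tracks the
    probability of *losing*, so the better option has the smaller theta and
    the inequality reverses.  Grid cells where the two thetas coincide
    contribute half their joint mass, preserving complementarity on the
    grid.
    """
    w = state._weights
    pc = state.density[state.option_index(chosen)] * w
    po = state.density[state.option_index(other)] * w
    pc = pc / pc.sum()
    po = po / po.sum()
    cum_below = np.concatenate(([0.0], np.cumsum(po)[:-1]))  # P(Y < theta_i)
    p_gt = float(np.sum(pc * (cum_below + 0.5 * po)))
    return p_gt if block == "gain" else 1.0 - p_gt


def context_value(ev_a: float, ev_b: float) -> float:
    """Mean expected value of the two options: the value of the decision context."""
    return (ev_a + ev_b) / 2.0


def prediction_error(outcome: int, ev_chosen: float) -> tuple[float, float]:
    """Signed prediction error (outcome minus EV of the chosen option) and |PE|."""
    pe = float(outcome) - ev_chosen
    return pe, abs(pe)


def confidence_change(conf_pre: float, conf_post: float) -> float:
    """Change in confidence for the chosen option across the outcome update."""
    return conf_post - conf_pre


LATENT_COLUMNS = [
    "confidence",
    "context",
    "variance",
    "ev_chosen",
    "ev_nonchosen",
    "pe",
    "abs_pe",
    "confidence_change",
    "choice_prob",
]


def extract_latents(
    designs: list[TrialDesign],
    choices: list[str],
    outcomes: list[int],
    params: ModelParams,
    K: int = DEFAULT_GRID_SIZE,
    spec: LikelihoodSpec = LikelihoodSpec(),
) -> pd.DataFrame:
    """Run the learner over a recorded session and extract the trial latents.

    Beliefs reset to uniform at each block start.  Decision-phase latents
    (confidence, context, variance, EVs) are computed from the pre-outcome
    beliefs; the prediction error compares the outcome with the pre-outcome
    EV; the confidence change compares confidence for the chosen option
    before and after the outcome update.
    """
    grid = np.linspace(0.0, 1.0, K)
    w = trapezoid_weights(grid)
    L = {o: likelihood_density(o, grid, spec) for o in (1, -1, 0)}
    g = params.gamma
    rows = []
    prev_block = None
    dens = None
    for design, choice, outcome in zip(designs, choices, outcomes):
        if design.block != prev_block:
            dens = np.ones((2, K))
            prev_block = design.block
        ci = OPTIONS.index(choice)
        oi = 1 - ci
        sign = 1.0 if design.block == "gain" else -1.0
        means = dens @ (grid * w)
        ev_c, ev_o = sign * means[ci], sign * means[oi]
        m2 = dens[ci] @ (grid**2 * w)
        var = float(m2 - means[ci] ** 2)
        conf_pre = _confidence_from_density(dens[ci], dens[oi], w, design.block)
        pe = float(outcome) - ev_c
        # outcome update
        post_c = g * dens[ci] * L[outcome] + (1.0 - g)
        post_o = g * dens[oi] + (1.0 - g)
        dens[ci] = post_c / (w @ post_c)
        dens[oi] = post_o / (w @ post_o)
        conf_post = _confidence_from_density(dens[ci], dens[oi], w, design.block)
        rows.append(
            {
                "block": design.block,
                "trial_in_block": design.trial_index,
                "trial_type": "exploitation" if design.is_exploitation else "learning",
                "choice": choice,
                "outcome": outcome,
                "confidence": conf_pre,
                "context": context_value(ev_c, ev_o),
                "variance": var,
                "ev_chosen": ev_c,
                "ev_nonchosen": ev_o,
                "pe": pe,
                "abs_pe": abs(pe),
                "confidence_change": conf_post - conf_pre,
                "choice_prob": choice_probability(ev_c, ev_o, params.temperature),
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    return df


def _confidence_from_density(
    dc: np.ndarray, do: np.ndarray, w: np.ndarray, block: str = "gain"
) -> float:
    pc = dc * w
    po = do * w
    pc = pc / pc.sum()
    po = po / po.sum()
    cum = np.concatenate(([0.0], np.cumsum(po)[:-1]))
    p_gt = float(np.sum(pc * (cum + 0.5 * po)))
    return p_gt if block == "gain" else 1.0 - p_gt


def ev_difference_series(
    blocks: np.ndarray,
    choices_idx: np.ndarray,
    outcomes: np.ndarray,
    gamma: float,
    K: int = DEFAULT_GRID_SIZE,
    spec: LikelihoodSpec = LikelihoodSpec(),
) -> np.ndarray:
    """Per-trial EV(chosen) - EV(non-chosen) under forgetting weight gamma.

    The belief trajectory does not depend on the temperature, so this series
    is all the likelihood needs; used by the fitting profile.  ``blocks`` is
    an array of "gain"/"loss", ``choices_idx`` of 0/1 option indices.
    """
    grid = np.linspace(0.0, 1.0, K)
    w = trapezoid_weights(grid)
    gw = grid * w
    L = {o: likelihood_density(o, grid, spec) for o in (1, -1, 0)}
    n = len(blocks)
    dev = np.empty(n)
    dens = np.ones((2, K))
    prev_block = None
    for t in range(n):
        if blocks[t] != prev_block:
            dens = np.ones((2, K))
            prev_block = blocks[t]
        ci = choices_idx[t]
        sign = 1.0 if blocks[t] == "gain" else -1.0
        means = dens @ gw
        dev[t] = sign * (means[ci] - means[1 - ci])
        post_c = gamma * dens[ci] * L[outcomes[t]] + (1.0 - gamma)
        post_o = gamma * dens[1 - ci] + (1.0 - gamma)
        dens[ci] = post_c / (w @ post_c)
        dens[1 - ci] = post_o / (w @ post_o)
    return dev


def write_latents(df: pd.DataFrame, path, participant=None) -> None:
    """Write a latents table as delimited text."""
    out = df.copy()
    if participant is not None and "participant" not in out.columns:
        out.insert(0, "participant", participant)
    out.to_csv(path, index=False)
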