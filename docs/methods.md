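# Methods

This note documents the models, numerical choices and limitations of
`mousebandit`. It covers what the code computes; no empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Task environment

The task is a volatile two-armed bandit: two options (red/blue, sides
randomized per trial) over two blocks of 180 trials (gain first by default;
block order is configurable because counterbalancing is not part of the
design constants). One option is "good". In the gain block the good option
yields +1 with probability 0.9, the other with 0.1; in the loss block the
semantics mirror under a sign flip — the *bad* option yields −1 with
probability 0.9, the good option with 0.1 — so that the good option is
always the better choice. The assignment swaps with hazard 0.2 per trial
(drawn i.i.d. from the second trial of a block onward; both options swap
simultaneously). Exploitation trials — the only trials whose outcome counts
toward the participant's points, starting from 40 — are placed by seeded
permutation with the exact count round(0.25 · n) per block, so the canonical
session has exactly 90 exploitation and 270 learning trials. Points may go
negative; an optional floor is configurable.

**Optimality** is defined against *experienced* probabilities: the optimal
choice at trial t is the option that was good at trial t − 1, even if the
schedule swapped underneath at t. The first trial of a block is undefined
and excluded from behaviour analyses. **Experience** counts trials since
the last switch event (0 at a block start or switch trial).

## The Bayesian learner

Beliefs over each option's outcome probability θ live on a grid of K = 201
equally spaced points including the endpoints; integrals use the trapezoid
rule. Endpoint inclusion is safe because both beta likelihoods vanish at
θ ∈ {0, 1}. All belief updates renormalize; normalization is preserved to
1e−9 over full sessions (tested). Grid-refinement behaviour: quantities of
smooth densities are stable to 1e−6 between K = 200 and 400; one-update
posteriors converge more slowly (~1e−3) because Beta(2, 1.1) has a
derivative singularity at θ = 1 — K = 201 keeps every tested quantity well
inside the tolerances used downstream.

The non-chosen option's printed update rule has a typographic gap in its
leading weight; it is implemented as γ·Pr + (1 − γ)·U(0,1), the reading
under which γ = 1 leaves the non-chosen belief unchanged, structurally
consistent with the chosen-option update.

**Confidence** is the probability that the *chosen option is better*. On
the grid it is the double sum P(θ_chosen > θ_other) with ties (equal grid
cells) contributing half their joint mass, which preserves exact
complementarity. In the loss block θ tracks the probability of losing, so
the better option has the smaller θ and the inequality reverses; without
this reversal, simulated learners' mean confidence falls below 0.5, which
contradicts the construct. The `confidence` function therefore takes a
`block` argument (default: the gain-block inequality).

**Variance** is the posterior variance of θ for the chosen option,
Var[θ] = ∫θ²Pr dθ − (∫θPr dθ)², computed before the outcome update. The
confidence change compares confidence for trial t's chosen option
immediately before vs immediately after that trial's outcome update.

Softmax probabilities are computed with max-subtraction and are finite for
|EV/T| up to at least 1e4.

## Fitting

The likelihood of a parameter pair (γ, T) is the product of softmax
probabilities of the observed exploitation-trial choices, with learning
applied on every trial. Because the belief trajectory — hence the per-trial
expected-value difference ΔEVₜ between chosen and non-chosen — depends only
on γ, the fit profiles T out: one belief pass per candidate γ caches ΔEVₜ,
and the 1-D temperature likelihood Σ log(1 + exp(−ΔEVₜ/T)) (convex in 1/T,
hence unimodal in log T) is minimized by bounded Brent search with explicit
boundary comparison. γ is searched on a coarse grid densified near 1
(where fitted values concentrate), then refined by bounded scalar
minimization on the bracketing interval. Bounds: γ ∈ [0, 1],
T ∈ [0.01, 10]; the lower temperature bound is part of the design, the
upper is a pragmatic cap for near-random responders. This profile search
replaces generic 2-D multi-start optimization; it is faster and immune to
the flat ridge the likelihood has in T when choices are near-deterministic.

Parameter recovery simulates agents choosing by softmax on their own
beliefs across a (γ, T) grid, refits each, and reports Spearman
correlations, bias and RMSE per parameter. At the canonical scale
(γ ∈ {0.9, 0.95, 0.99} × T ∈ {0.05, 0.2, 1}, 20 agents per cell, 360
trials) rank correlations are ≈0.6 (γ) and ≈0.75 (T); γ is only weakly
identified for noisy agents (high T), which is expected — a near-random
chooser reveals little about its learning.

## Synthetic cursor trajectories

The generator is a fixture generator with controllable latent-feature
coupling, not a model of motor control. Geometry emulates the task screen:
1536 × 864 px, start circle at (768, 780) radius 40, targets at (368, 200)
and (1168, 200) radius 50, sampled at 100 Hz with start jitter
Uniform(−5, 5) px per axis and Gaussian positional noise (1 px), rounded to
integer pixels as a real recording would be.

A decision path is a minimum-jerk polynomial from start to the chosen
target's edge plus a lateral pull perpendicular to the straight line,
peaking mid-movement (sin² profile), signed toward the non-chosen option.
Its amplitude is β_conf·(1 − confidence) + β_ctx·(0.5 − context) plus a
symmetric trial-to-trial perturbation (SD 10 px) so that signed deviation
measures vary in both directions. A "deviant" phenotype (large loop toward
the distractor plus near-certain hovering) is drawn with probability
sigmoid(logit(0.11) + 4·(0.65 − confidence)); 0.65 is the typical mean
confidence of simulated learners, making the marginal deviant share ≈ the
11% minority phenotype the clustering stage is meant to recover. Movement
duration scales multiplicatively with (1 − confidence) and (0.5 − context);
hovers (zero-velocity plateaus of 280–700 ms) are inserted with probability
increasing in (1 − confidence). Return paths run from the choice point back
to the start circle with lateral drift −β_pe·PE, duration increasing in
|PE|, and hover probability increasing in |PE|. All coefficients are free
configuration; setting them to zero yields a null generator in which no
latent-feature association exists (used for calibration tests).

What the generator does *not* emulate: autocorrelated motor noise,
submovement structure, velocity asymmetries, device quantization beyond
integer pixels, or any fitted correspondence to human kinematics. Passing
tests therefore certify the pipeline's statistical machinery, not claims
about real movements.

## Preprocessing

Pipeline order: exclusion → mirroring → splitting → alignment.

* **Exclusion**: a trial is dropped when its first sample deviates more
  than 20 px from the expected start on either axis (exactly 20 is
  retained — the criterion is a maximum allowed deviation).
* **Mirroring**: right-choice trials reflect about the vertical axis
  through the start, so all paths lead left.
* **Splitting**: the decision path ends at the first sample at or inside
  the chosen option's edge; the return path runs from that sample to the
  first sample at or inside the start circle. Paths that never reach the
  required boundary raise a malformed-trial error (reported, not dropped
  silently).
* **Alignment**: translation plus independent per-axis linear scaling — the
  minimal affine map forcing first sample to (0, 0) and last to
  (−250, 350). A translation-only variant cannot force common endpoints
  for every path; per-axis rescaling is the minimal map that does. The y axis flips sign in the process
  (screen y grows downward; aligned y grows upward toward the targets).
  Timestamps and sample counts are untouched; collinearity is preserved.

All dynamics measures are computed in aligned space.

## Action dynamics

Thirty measures per path. Conventions that matter:

* Deviation sign: positive = toward the non-chosen option's side
  ("above" the direct path), so coefficients read as distractor attraction.
* MAD is the deviation of largest magnitude with its sign and timepoint;
  md_above/md_below are the signed extrema; AD the mean; AUC the signed
  net area over progression along the direct axis (an absolute-area variant
  is a config switch).
* Flips count direction changes per axis after collapsing zero increments,
  with a distance threshold defaulting to 0; reversals count transversal
  crossings of the start-anchored axis lines.
* Timing: RT = last − first timestamp; initiation time until displacement
  from the first sample exceeds 0 px; idle time sums intervals with
  displacement ≤ 0 px (exact stillness — meaningful because logs are
  integer pixels; the epsilon is configurable); a hover is a maximal idle
  run ≥ 250 ms by default; the threshold is configurable (e.g. a stricter
  100-ms variant) since conventions differ between studies.
* Kinematics: finite differences on duplicate-timestamp-merged samples;
  velocities at interval midpoints, accelerations at the shared interior
  sample. No smoothing — deliberate, to match the field's standard toolkit
  behaviour.
* Entropy: sample entropy of the first-differenced x series, m = 3,
  r = 0.2 · SD, with template counts restricted to indices that admit an
  (m+1)-extension, so perfectly regular series give exactly 0. Returned as
  missing when no template pair matches.

Every measure matches an independent loop-based reimplementation to 1e−9
(counts exactly) on random polylines, including degenerate features such as
stationary intervals and duplicate timestamps.

## Clustering

Paths are resampled to P = 100 points equally spaced in cumulative arc
length (linear interpolation, time discarded) and clustered by Ward linkage
on the concatenated coordinates. The number of clusters is chosen by the
largest relative jump in dendrogram merge heights over k ∈ [2, 10] — the
minimum of two clusters is a hard floor. Labels are deterministically
ordered by ascending mean |MAD|, so label 1 is always the most direct
phenotype, fixing the sign convention of the cluster-membership logistic
models. An all-identical input set triggers a degenerate-split warning
rather than an arbitrary partition. P and the linkage method are free
choices of this implementation; both are configurable.

## Mixed-model linkage

Predictors: Experience → (experience − 1)/5; trial type and gain/loss as
±0.5 dummies; each latent mean-centered and divided by its range (method
configurable: range/SD/none; range-scaling spans each latent over ≈1
unit, keeping coefficients comparable across latents).

Families per measure: counts → Poisson GLMM; zero-inflated nonnegative
measures → hurdle lognormal (logistic zero-vs-nonzero part + linear mixed
model on log positives, reported as two parts, model AIC = sum of parts);
binary (sign of MAD) → logistic GLMM; right-skewed positive measures →
linear mixed model on logs; the rest → linear mixed models. The
minimum-x measure enters its hurdle as −(min_x + 250) so the excess mass at
the target x sits at zero. All models carry a by-subject random intercept
and no random slopes.

Logistic and Poisson GLMMs are fitted by maximum likelihood with the random
intercept integrated out by *adaptive* Gauss-Hermite quadrature (15 nodes;
per-group Newton mode-finding with curvature rescaling). Non-adaptive
quadrature is not sufficient: with many informative observations per group
the integrand is much narrower than the node spacing and the fixed-node
estimate is visibly biased (the test suite pins the adaptive implementation
against lme4's `glmer` with nAGQ = 25 to ~1e−3). Gradients use the Fisher
identity (posterior expectation of the joint score); standard errors come
from the numeric Hessian; inference is Wald-z. Linear mixed models use
statsmodels MixedLM with ML (not REML) so AICs are comparable across fixed
effects; when the random-intercept variance estimate collapses to zero and
the profiled Hessian is singular, the model provably reduces to OLS, which
is used as the fallback. p-values for linear models are Wald-normal —
the uniform inference choice across all families here.

Alpha levels: 0.05 for choice/cluster models, 0.005 for the per-measure
dynamics battery — a deliberate partial compensation for the correlated
multiple comparisons, not a formal correction.

The Context-vs-Gain/Loss comparison refits every decision-phase measure
with the Context predictor replaced by the block dummy and tabulates AIC
differences (negative favours Context), winner counts, the mean difference,
and whether each difference clears the rule-of-thumb margin of 2.

Calibration, tested: under the null generator the per-test false-positive
counts at both alpha levels stay inside the central 99% binomial region of
the nominal rate over 200 replicates (10 participants × 48 trials each);
with the generator's default couplings the confidence coefficients on
log RT and log |MAD| are negative in ≥ 90% of replicates.

## Problem sizes and determinism

Default test and acceptance scales are chosen to exercise every stage at
statistically meaningful but desk-friendly sizes: six participants × 120
trials for pipeline fixtures, 180 agents for recovery, 200 replicates at 10
participants × 48 trials for calibration. The full study scale (115
participants × 360 trials, trajectories on all trials) is a single
configuration change. Every stochastic stage takes an explicit seed; the
pipeline derives per-stage child seeds from one global seed via
`SeedSequence`, so stages are independently reproducible and a fixed config
+ seed yields byte-identical outputs.

## Known limitations

* The trajectory generator's couplings are linear and monotone by
  construction; it cannot produce interactions between latents and movement
  features, so the linkage stage's power against such patterns is untested.
* Wald inference in small samples is approximate; the calibration tests
  bound its behaviour only at the scales they run.
* The hurdle model's two parts share no cross-part correlation.
* γ is weakly identified for high-temperature agents; recovery summaries
  should be read per-cell, not only pooled.
* Sample entropy on short paths (< m + 2 increments) is reported missing,
  and its value depends on the sampling rate; comparisons are only valid
  within a fixed recording setup.
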