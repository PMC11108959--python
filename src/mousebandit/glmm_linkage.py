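"""Mixed-model linkage between model latents and movement measures.

Three model families link trial-level latent variables to behaviour and
action dynamics, all with a by-subject random intercept:

* logistic and Poisson GLMMs, fitted by maximum likelihood with the random
  intercept integrated out by Gauss-Hermite quadrature (implemented here;
  statsmodels offers no frequentist GLMM) — Wald z tests, true
  log-likelihood and hence AIC;
* linear mixed models (optionally on log-transformed responses) through
  statsmodels MixedLM with ML estimation;
* hurdle lognormal models for zero-inflated measures, reported as two parts:
  a logistic GLMM on zero vs nonzero and a linear mixed model on the log of
  the positive values.

Predictors are centered and range-scaled; Experience is centered at 1 and
divided by 5; trial type and gain/loss enter as +/-0.5 dummies.  The alpha
level is 0.05 for choice/cluster models and 0.005 for the action-dynamics
battery (a partial multiple-comparison compensation, not a formal
correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import norm
import statsmodels.api as sm

from .task_env import label_optimality

ALPHA_CHOICE = 0.05
ALPHA_DYNAMICS = 0.005

DECISION_PREDICTORS = ["confidence_c", "variance_c", "context_c"]
RETURN_PREDICTORS = ["pe_c", "abs_pe_c", "confidence_change_c", "outcome_c"]


# ---------------------------------------------------------------------------
# Gauss-Hermite random-intercept GLMM
# ---------------------------------------------------------------------------


@dataclass
class GLMMResult:
    params: np.ndarray  # fixed effects
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    re_sd: float
    llf: float
    aic: float
    converged: bool
    names: list[str]
    n_obs: int
    n_groups: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.names,
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


class RandomInterceptGLMM:
    """ML random-intercept GLMM (binomial or Poisson, canonical link).

    The scalar random effect is integrated out by adaptive Gauss-Hermite
    quadrature: for each group the quadrature nodes are recentered at the
    conditional mode of the random effect (found by Newton iteration) and
    rescaled by the local curvature, as lme4/GLMMadaptive do — plain
    Gauss-Hermite misses the sharply peaked per-group integrands that arise
    with informative groups.  The marginal likelihood is maximized by
    L-BFGS-B with a Fisher-identity gradient (posterior expectation of the
    joint score); Wald standard errors come from the numerical Hessian at
    the optimum.
    """

    def __init__(self, family: str, n_quad: int = 15):
        if family not in ("binomial", "poisson"):
            raise ValueError(f"unsupported family {family!r}")
        self.family = family
        nodes, weights = hermegauss(n_quad)
        self._nodes = nodes
        self._logw = np.log(weights)

    def _mu_logp(self, y, eta):
        if self.family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            logp = y * eta - np.logaddexp(0.0, eta)
            dmu = mu * (1.0 - mu)
        else:
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
            logp = y * eta - mu - gammaln(y + 1.0)
            dmu = mu
        return mu, logp, dmu

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray,
        names: list[str] | None = None,
    ) -> GLMMResult:
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        order = np.argsort(groups, kind="stable")
        y, X, groups = y[order], X[order], np.asarray(groups)[order]
        _, starts = np.unique(groups, return_index=True)
        sub = np.searchsorted(starts, np.arange(len(y)), side="right") - 1
        k = X.shape[1]
        n_groups = len(starts)
        z, logw = self._nodes, self._logw
        warm = {"modes": np.zeros(n_groups)}

        def nll_grad(params):
            beta, sd = params[:k], np.exp(params[k])
            var = max(sd**2, 1e-12)
            eta0 = X @ beta
            # Newton iteration for the conditional modes b_i
            b = warm["modes"].copy()
            for _ in range(25):
                mu, _, dmu = self._mu_logp(y, eta0 + b[sub])
                score = np.add.reduceat(y - mu, starts) - b / var
                hess = -np.add.reduceat(dmu, starts) - 1.0 / var
                step = score / hess
                b -= np.clip(step, -5 * sd - 1, 5 * sd + 1)
                if np.max(np.abs(step)) < 1e-10:
                    break
            warm["modes"] = b
            mu, _, dmu = self._mu_logp(y, eta0 + b[sub])
            curv = np.add.reduceat(dmu, starts) + 1.0 / var  # -g''(mode)
            sigma = 1.0 / np.sqrt(curv)
            # adaptive nodes b_iq = mode_i + sigma_i * z_q
            bq = b[:, None] + sigma[:, None] * z[None, :]
            etaQ = eta0[:, None] + bq[sub, :]
            muQ, logpQ, _ = self._mu_logp(y[:, None], etaQ)
            g = (
                np.add.reduceat(logpQ, starts, axis=0)
                - bq**2 / (2 * var)
                - 0.5 * np.log(2 * np.pi * var)
            )
            S = logw[None, :] + g + z[None, :] ** 2 / 2
            Ls = logsumexp(S, axis=1) + np.log(sigma)
            post = np.exp(S - (Ls - np.log(sigma))[:, None])
            post /= post.sum(axis=1, keepdims=True)
            # Fisher identity: gradient = posterior expectation of joint score
            w_obs = post[sub, :]
            r = (y[:, None] - muQ) * w_obs
            gbeta = X.T @ r.sum(axis=1)
            gsd = float((post * (bq**2 / var - 1.0)).sum())
            return -float(Ls.sum()), -np.concatenate([gbeta, [gsd]])

        # start from a no-random-effect GLM
        fam = sm.families.Binomial() if self.family == "binomial" else sm.families.Poisson()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                beta0 = sm.GLM(y, X, family=fam).fit().params
            except Exception:
                beta0 = np.zeros(k)
        x0 = np.concatenate([beta0, [np.log(0.5)]])
        res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B")
        params = res.x
        llf = -res.fun
        # numerical Hessian from central differences of the gradient
        eps = 1e-5
        H = np.empty((k + 1, k + 1))
        for i in range(k + 1):
            e = np.zeros(k + 1)
            e[i] = eps
            gp = nll_grad(params + e)[1]
            gm = nll_grad(params - e)[1]
            H[i] = (gp - gm) / (2 * eps)
        H = (H + H.T) / 2
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(k, np.nan)
        beta = params[:k]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / bse
        p = 2 * norm.sf(np.abs(z))
        return GLMMResult(
            params=beta,
            bse=bse,
            zvalues=z,
            pvalues=p,
            re_sd=float(np.exp(params[k])),
            llf=llf,
            aic=float(2 * (k + 1) - 2 * llf),
            converged=bool(res.success),
            names=names or [f"x{i}" for i in range(k)],
            n_obs=len(y),
            n_groups=len(starts),
        )


def fit_linear_mixed(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, names: list[str]
) -> GLMMResult:
    """Linear mixed model (by-subject random intercept) via statsmodels, ML.

    When the random-intercept variance estimate collapses to zero the mixed
    profile Hessian is singular; the model then reduces to ordinary least
    squares, which is fitted instead (with the zero variance reported).
    """
    k = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.regression.mixed_linear_model.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=False)
            # force lazy evaluations inside the warning guard
            _ = np.asarray(fit.bse_fe)
            llf = float(fit.llf)
        except np.linalg.LinAlgError:
            ols = sm.OLS(y, X).fit()
            z0 = ols.params / ols.bse
            return GLMMResult(
                params=np.asarray(ols.params),
                bse=np.asarray(ols.bse),
                zvalues=np.asarray(z0),
                pvalues=2 * norm.sf(np.abs(z0)),
                re_sd=0.0,
                llf=float(ols.llf),
                aic=float(2 * (k + 1) - 2 * ols.llf),
                converged=True,
                names=names,
                n_obs=len(y),
                n_groups=int(pd.Series(groups).nunique()),
            )
    params = np.asarray(fit.fe_params)
    bse = np.asarray(fit.bse_fe)
    z = params / bse
    p = 2 * norm.sf(np.abs(z))
    n_par = k + 2  # fixed effects + random-intercept variance + residual variance
    return GLMMResult(
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=p,
        re_sd=float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
        llf=llf,
        aic=float(2 * n_par - 2 * llf),
        converged=bool(fit.converged),
        names=names,
        n_obs=len(y),
        n_groups=int(pd.Series(groups).nunique()),
    )


# ---------------------------------------------------------------------------
# Predictor preparation
# ---------------------------------------------------------------------------


def prepare_predictors(df: pd.DataFrame, scale_method: str = "range") -> pd.DataFrame:
    """Add centered/scaled predictor columns to a trials+latents table.

    Experience becomes (experience - 1) / 5; trial type and block become
    +/-0.5 dummies; each latent is mean-centered and, with the default
    "range" method, divided by its range so it spans about one unit.
    """
    out = df.copy()
    if "experience" in out.columns:
        out["experience_s"] = (out["experience"] - 1.0) / 5.0
    if "trial_type" in out.columns:
        out["trial_type_d"] = np.where(out["trial_type"] == "exploitation", 0.5, -0.5)
    if "block" in out.columns:
        out["gainloss_d"] = np.where(out["block"] == "gain", 0.5, -0.5)
    for col in ("confidence", "variance", "context", "pe", "abs_pe", "confidence_change", "outcome"):
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        centered = x - x.mean()
        if scale_method == "range":
            rng = x.max() - x.min()
            out[f"{col}_c"] = centered / rng if rng > 0 else centered
        elif scale_method == "sd":
            sd = x.std()
            out[f"{col}_c"] = centered / sd if sd > 0 else centered
        elif scale_method == "none":
            out[f"{col}_c"] = centered
        else:
            raise ValueError(f"unknown scale_method {scale_method!r}")
    return out


def _design(df: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str]]:
    missing = [p for p in predictors if p not in df.columns]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    return X, ["intercept"] + predictors


# ---------------------------------------------------------------------------
# Behaviour (optimality) model
# ---------------------------------------------------------------------------


def fit_behavior_model(trials: pd.DataFrame, interaction: bool = True) -> GLMMResult:
    """Logistic mixed model of choice optimality on Experience and Trial type.

    Optimality is defined against experienced probabilities (the previous
    trial's good option); first trials of each block are removed.  The model
    has a by-subject random intercept; alpha level 0.05.
    """
    parts = []
    for participant, g in trials.groupby("participant", sort=True):
        g = g.sort_values("trial").copy()
        from .synthetic_data import _designs_from_frame

        labels = label_optimality(_designs_from_frame(g), list(g["choice"]))
        g["optimal"] = [None if l is None else float(l == "optimal") for l in labels]
        parts.append(g)
    df = pd.concat(parts, ignore_index=True)
    df = df[df["optimal"].notna()].copy()
    df = prepare_predictors(df)
    predictors = ["experience_s", "trial_type_d"]
    if interaction:
        df["experience_x_trialtype"] = df["experience_s"] * df["trial_type_d"]
        predictors.append("experience_x_trialtype")
    X, names = _design(df, predictors)
    model = RandomInterceptGLMM("binomial")
    return model.fit(df["optimal"].to_numpy(float), X, df["participant"].to_numpy(), names)


def fit_cluster_model(
    clusters: pd.DataFrame, trials: pd.DataFrame, phase: str, scale_method: str = "range"
) -> GLMMResult:
    """Logistic mixed model of path type (1 = most direct) on the phase latents."""
    predictors = DECISION_PREDICTORS if phase == "decision" else RETURN_PREDICTORS
    df = clusters[clusters["phase"] == phase].merge(
        prepare_predictors(trials, scale_method), on=["participant", "trial"]
    )
    y = (df["cluster"] > 1).astype(float)  # 1: deviant path type
    X, names = _design(df, predictors)
    return RandomInterceptGLMM("binomial").fit(y.to_numpy(), X, df["participant"].to_numpy(), names)


# ---------------------------------------------------------------------------
# Action-dynamics models
# ---------------------------------------------------------------------------

# measure -> (family, transform); transforms map the measure onto the scale
# the family expects.  "hurdle" families state the nonnegative transform
# whose zeros form the binary part.
FAMILY_MAP: dict[str, tuple[str, str]] = {
    "max_x": ("hurdle_lognormal", "identity"),
    "min_x": ("hurdle_lognormal", "reflect_250"),  # -(min_x + 250): excess at 0
    "max_y": ("linear", "identity"),
    "min_y": ("hurdle_lognormal", "negate"),
    "mad_signed": ("logistic", "sign"),
    "mad_abs": ("linear_log", "identity"),
    "mad_time": ("linear_log", "identity"),
    "md_above": ("hurdle_lognormal", "positive_part"),
    "md_below": ("hurdle_lognormal", "negative_part"),
    "md_above_time": ("linear", "identity"),
    "md_below_time": ("linear", "identity"),
    "ad": ("linear", "identity"),
    "auc": ("linear", "identity"),
    "flips_x": ("poisson", "identity"),
    "flips_y": ("poisson", "identity"),
    "reversals_x": ("poisson", "identity"),
    "reversals_y": ("poisson", "identity"),
    "rt": ("linear_log", "identity"),
    "initiation_time": ("linear_log", "identity"),
    "idle_time": ("hurdle_lognormal", "identity"),
    "hover_time": ("hurdle_lognormal", "identity"),
    "n_hovers": ("poisson", "identity"),
    "total_distance": ("linear_log", "identity"),
    "max_velocity": ("linear_log", "identity"),
    "max_velocity_time": ("linear", "identity"),
    "max_acceleration": ("linear", "identity"),
    "max_acceleration_time": ("linear", "identity"),
    "min_acceleration": ("linear", "identity"),
    "min_acceleration_time": ("linear", "identity"),
    "entropy": ("linear", "identity"),
}

_TRANSFORMS = {
    "identity": lambda y: y,
    "negate": lambda y: -y,
    "reflect_250": lambda y: -(y + 250.0),
    "positive_part": lambda y: np.maximum(y, 0.0),
    "negative_part": lambda y: np.maximum(-y, 0.0),
    "sign": lambda y: (y > 0).astype(float),
}


def fit_dynamics_models(
    features: pd.DataFrame,
    trials: pd.DataFrame,
    phase: str,
    alpha: float = ALPHA_DYNAMICS,
    family_map: dict | None = None,
    scale_method: str = "range",
    predictors: list[str] | None = None,
    exploitation_only: bool = True,
) -> pd.DataFrame:
    """Fit one mixed model per action-dynamics measure; tidy results table.

    Decision-phase predictors are Confidence, Variance and Context; return
    phase PE, |PE|, Confidence change and Outcome.  Hurdle models appear as
    two rows per predictor (binary and truncated parts).  Non-converged or
    degenerate fits are flagged, never silently dropped.
    """
    family_map = family_map or FAMILY_MAP
    if predictors is None:
        predictors = DECISION_PREDICTORS if phase == "decision" else RETURN_PREDICTORS
    df = features[features["phase"] == phase].merge(
        prepare_predictors(trials, scale_method), on=["participant", "trial"]
    )
    if exploitation_only and "trial_type_x" in df.columns:
        df = df[df["trial_type_x"] == "exploitation"]
    elif exploitation_only and "trial_type" in df.columns:
        df = df[df["trial_type"] == "exploitation"]
    rows = []
    for measure, (family, transform) in family_map.items():
        if measure not in df.columns:
            continue
        sub = df[df[measure].notna()]
        for part_rows in _fit_one_measure(sub, measure, family, transform, predictors, alpha):
            rows.append(part_rows)
    return pd.DataFrame(rows)


def _fit_one_measure(df, measure, family, transform, predictors, alpha):
    y_raw = _TRANSFORMS[transform](df[measure].to_numpy(float))
    groups = df["participant"].to_numpy()
    rows = []

    def tidy(result: GLMMResult, part: str, note: str = ""):
        for name, est, se, z, p in zip(
            result.names, result.params, result.bse, result.zvalues, result.pvalues
        ):
            rows.append(
                {
                    "measure": measure,
                    "family": family,
                    "part": part,
                    "predictor": name,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "aic": result.aic,
                    "converged": result.converged,
                    "n": result.n_obs,
                    "note": note,
                }
            )

    try:
        if family == "linear":
            X, names = _design(df, predictors)
            tidy(fit_linear_mixed(y_raw, X, groups, names), "mean")
        elif family == "linear_log":
            pos = y_raw > 0
            sub = df[pos]
            X, names = _design(sub, predictors)
            tidy(
                fit_linear_mixed(np.log(y_raw[pos]), X, sub["participant"].to_numpy(), names),
                "mean",
                note="" if pos.all() else f"{int((~pos).sum())} nonpositive values dropped",
            )
        elif family == "logistic":
            X, names = _design(df, predictors)
            if len(np.unique(y_raw)) < 2:
                rows.append(_degenerate_row(measure, family, "binary", "constant response"))
            else:
                tidy(RandomInterceptGLMM("binomial").fit(y_raw, X, groups, names), "binary")
        elif family == "poisson":
            X, names = _design(df, predictors)
            tidy(RandomInterceptGLMM("poisson").fit(y_raw, X, groups, names), "mean")
        elif family == "hurdle_lognormal":
            nz = y_raw > 0
            X, names = _design(df, predictors)
            if nz.all() or not nz.any():
                rows.append(
                    _degenerate_row(
                        measure, family, "binary", "degenerate zero pattern; truncated part skipped"
                    )
                )
            else:
                tidy(
                    RandomInterceptGLMM("binomial").fit(nz.astype(float), X, groups, names),
                    "binary",
                )
                sub = df[nz]
                Xp, names_p = _design(sub, predictors)
                tidy(
                    fit_linear_mixed(
                        np.log(y_raw[nz]), Xp, sub["participant"].to_numpy(), names_p
                    ),
                    "truncated",
                )
        else:
            raise ValueError(f"unknown family {family!r} for measure {measure!r}")
    except Exception as err:  # record, don't hide
        rows.append(_degenerate_row(measure, family, "error", str(err)))
    return rows


def _degenerate_row(measure, family, part, note):
    return {
        "measure": measure,
        "family": family,
        "part": part,
        "predictor": None,
        "estimate": np.nan,
        "se": np.nan,
        "z": np.nan,
        "p": np.nan,
        "significant": False,
        "aic": np.nan,
        "converged": False,
        "n": 0,
        "note": note,
    }


# ---------------------------------------------------------------------------
# Context vs Gain/Loss AIC comparison
# ---------------------------------------------------------------------------


def compare_context_vs_gainloss(
    features: pd.DataFrame,
    trials: pd.DataFrame,
    phase: str = "decision",
    family_map: dict | None = None,
    scale_method: str = "range",
    exploitation_only: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Refit each measure with Context replaced by a Gain/Loss dummy; compare AIC.

    Returns a per-measure table with both AICs and their difference
    (context minus gain/loss; negative favours the Context model) and a
    summary with winner counts, the mean difference, and how many
    differences exceed the rule-of-thumb margin of 2.
    """
    base = DECISION_PREDICTORS if phase == "decision" else RETURN_PREDICTORS
    if "context_c" not in base:
        raise ValueError("comparison applies to models that include Context")
    alt = [p if p != "context_c" else "gainloss_d" for p in base]
    res_ctx = fit_dynamics_models(
        features, trials, phase, family_map=family_map, scale_method=scale_method,
        predictors=base, exploitation_only=exploitation_only,
    )
    res_gl = fit_dynamics_models(
        features, trials, phase, family_map=family_map, scale_method=scale_method,
        predictors=alt, exploitation_only=exploitation_only,
    )

    def model_aic(res: pd.DataFrame) -> pd.Series:
        # hurdle models: sum the parts' AICs
        ok = res[res["predictor"].notna()]
        return ok.groupby("measure")[["aic", "part"]].apply(
            lambda g: g.drop_duplicates("part")["aic"].sum()
        )

    a_ctx = model_aic(res_ctx)
    a_gl = model_aic(res_gl)
    table = pd.DataFrame({"aic_context": a_ctx, "aic_gainloss": a_gl}).dropna()
    table["delta_aic"] = table["aic_context"] - table["aic_gainloss"]
    table["winner"] = np.where(table["delta_aic"] < 0, "context", "gainloss")
    table["substantial"] = table["delta_aic"].abs() >= 2.0
    summary = {
        "n_measures": int(len(table)),
        "context_wins": int((table["winner"] == "context").sum()),
        "gainloss_wins": int((table["winner"] == "gainloss").sum()),
        "mean_delta_aic": float(table["delta_aic"].mean()) if len(table) else np.nan,
        "n_substantial": int(table["substantial"].sum()),
    }
    return table.reset_index().rename(columns={"index": "measure"}), summary
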