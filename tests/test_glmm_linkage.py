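import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mousebandit as mb
from mousebandit.clustering import cluster_aligned_paths
from mousebandit.glmm_linkage import (
    FAMILY_MAP,
    RandomInterceptGLMM,
    compare_context_vs_gainloss,
    fit_behavior_model,
    fit_cluster_model,
    fit_dynamics_models,
    fit_linear_mixed,
    prepare_predictors,
)


def _mixed_logistic_data(rng, n_sub=20, n_tr=40, re_sd=0.7):
    sub = np.repeat(np.arange(n_sub), n_tr)
    x1 = rng.normal(size=n_sub * n_tr)
    x2 = rng.normal(size=n_sub * n_tr)
    b = rng.normal(0, re_sd, n_sub)
    eta = 0.4 + 0.8 * x1 - 0.3 * x2 + b[sub]
    y = (rng.random(n_sub * n_tr) < 1 / (1 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(len(y)), x1, x2])
    return y, X, sub


class TestPreparePredictors:
    def test_experience_transform(self):
        df = pd.DataFrame({"experience": [1, 0, 43]})
        out = prepare_predictors(df)
        assert out["experience_s"].tolist() == pytest.approx([0.0, -0.2, 8.4])

    def test_dummies(self):
        df = pd.DataFrame(
            {"trial_type": ["exploitation", "learning"], "block": ["gain", "loss"]}
        )
        out = prepare_predictors(df)
        assert out["trial_type_d"].tolist() == [0.5, -0.5]
        assert out["gainloss_d"].tolist() == [0.5, -0.5]

    def test_latents_centered_and_range_scaled(self, rng):
        df = pd.DataFrame({"confidence": rng.uniform(0.2, 0.9, 200)})
        out = prepare_predictors(df)
        assert out["confidence_c"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["confidence_c"].max() - out["confidence_c"].min() == pytest.approx(1.0)

    def test_missing_columns_raise_downstream(self):
        from mousebandit.glmm_linkage import _design

        with pytest.raises(KeyError):
            _design(pd.DataFrame({"a": [1.0]}), ["confidence_c"])


class TestRandomInterceptGLMM:
    def test_matches_lme4_binomial(self, rng, tmp_path):
        y, X, sub = _mixed_logistic_data(rng)
        res = RandomInterceptGLMM("binomial", n_quad=25).fit(y, X, sub, ["i", "x1", "x2"])
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2], "sub": sub})
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        r_code = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ x1 + x2 + (1|sub), data=d, family=binomial, nAGQ=25);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert res.params == pytest.approx(ref[:3], abs=2e-3)
        assert res.re_sd == pytest.approx(ref[3], abs=2e-3)
        assert res.llf == pytest.approx(ref[4], abs=1e-2)

    def test_matches_lme4_poisson(self, rng, tmp_path):
        n_sub, n_tr = 15, 30
        sub = np.repeat(np.arange(n_sub), n_tr)
        x = rng.normal(size=n_sub * n_tr)
        b = rng.normal(0, 0.5, n_sub)
        y = rng.poisson(np.exp(0.5 + 0.4 * x + b[sub])).astype(float)
        X = np.column_stack([np.ones(len(y)), x])
        res = RandomInterceptGLMM("poisson", n_quad=25).fit(y, X, sub, ["i", "x"])
        df = pd.DataFrame({"y": y, "x": x, "sub": sub})
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        r_code = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ x + (1|sub), data=d, family=poisson, nAGQ=25);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert res.params == pytest.approx(ref[:2], abs=2e-3)
        assert res.re_sd == pytest.approx(ref[2], abs=5e-3)

    def test_reduces_to_glm_without_group_variance(self, rng):
        y, X, sub = _mixed_logistic_data(rng, re_sd=0.0)
        res = RandomInterceptGLMM("binomial").fit(y, X, sub, ["i", "x1", "x2"])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert res.params == pytest.approx(np.asarray(glm.params), abs=0.05)

    def test_unsupported_family_rejected(self):
        with pytest.raises(ValueError):
            RandomInterceptGLMM("gamma")

    def test_linear_mixed_ols_fallback(self, rng):
        # no group variance: the mixed fit reduces to OLS within tolerance
        n = 300
        sub = np.repeat(np.arange(10), 30)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        res = fit_linear_mixed(y, X, sub, ["i", "x"])
        ols = sm.OLS(y, X).fit()
        assert res.params == pytest.approx(np.asarray(ols.params), abs=0.02)


class TestBehaviorModel:
    def test_learning_shows_positive_experience_effect(self, small_dataset):
        trials, _ = small_dataset
        res = fit_behavior_model(trials)
        coef = dict(zip(res.names, res.params))
        pval = dict(zip(res.names, res.pvalues))
        assert coef["experience_s"] > 0
        assert pval["experience_s"] < 0.05

    def test_coefficient_count_matches_specification(self, small_dataset):
        trials, _ = small_dataset
        res = fit_behavior_model(trials, interaction=False)
        assert res.names == ["intercept", "experience_s", "trial_type_d"]
        assert len(res.params) == 3


@pytest.fixture(scope="module")
def decision_results(features_small, small_dataset):
    trials, _ = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_dynamics_models(features_small, trials, "decision")


class TestDynamicsModels:
    def test_every_measure_reported(self, decision_results):
        assert set(decision_results["measure"]) == set(FAMILY_MAP)

    def test_no_silent_predictor_drops(self, decision_results):
        ok = decision_results[decision_results["predictor"].notna()]
        per_part = ok.groupby(["measure", "part"])["predictor"].count()
        assert (per_part == 4).all()  # intercept + three decision latents

    def test_confidence_reduces_deviation(self, decision_results):
        row = decision_results[
            (decision_results.measure == "mad_abs")
            & (decision_results.predictor == "confidence_c")
        ].iloc[0]
        assert row["estimate"] < 0
        assert row["p"] < 0.05

    def test_hurdle_reported_in_two_parts(self, decision_results):
        parts = set(
            decision_results[decision_results.measure == "idle_time"]["part"]
        )
        assert {"binary", "truncated"} <= parts or "error" in parts

    def test_degenerate_hurdle_flagged(self, small_dataset, features_small):
        trials, _ = small_dataset
        feats = features_small.copy()
        feats["idle_time"] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_dynamics_models(
                feats, trials, "decision", family_map={"idle_time": ("hurdle_lognormal", "identity")}
            )
        assert (res["part"] == "binary").any()
        assert "degenerate" in res.iloc[0]["note"]

    def test_cluster_membership_follows_confidence(self, aligned_small, small_dataset):
        trials, _ = small_dataset
        aligned, _ = aligned_small
        labels, _, _ = cluster_aligned_paths(aligned, "decision", P=50)
        res = fit_cluster_model(labels, trials, "decision")
        coef = dict(zip(res.names, res.params))
        # higher confidence -> more direct path (lower odds of the deviant type)
        assert coef["confidence_c"] < 0


class TestContextComparison:
    def test_winner_bookkeeping(self, features_small, small_dataset):
        trials, _ = small_dataset
        fam = {k: FAMILY_MAP[k] for k in ("rt", "mad_abs", "flips_x", "auc", "idle_time")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, summary = compare_context_vs_gainloss(
                features_small, trials, "decision", family_map=fam
            )
        assert summary["n_measures"] == len(table)
        assert summary["context_wins"] + summary["gainloss_wins"] == summary["n_measures"]
        assert np.isfinite(summary["mean_delta_aic"])

    def test_identical_specifications_tie(self, features_small, small_dataset):
        trials, _ = small_dataset
        fam = {"rt": FAMILY_MAP["rt"]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_dynamics_models(features_small, trials, "decision", family_map=fam)
            b = fit_dynamics_models(features_small, trials, "decision", family_map=fam)
        assert a["aic"].iloc[0] == pytest.approx(b["aic"].iloc[0], abs=1e-9)

    def test_return_phase_has_no_context(self, features_small, small_dataset):
        trials, _ = small_dataset
        with pytest.raises(ValueError):
            compare_context_vs_gainloss(features_small, trials, "return")
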