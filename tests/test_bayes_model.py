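import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mousebandit.bayes_model as bm
from mousebandit.task_env import ConfigurationError, TrialDesign


class TestInitAndLikelihood:
    def test_uniform_prior_mean_half(self):
        state = bm.init_beliefs(200)
        for opt in ("red", "blue"):
            assert state.mean(opt) == pytest.approx(0.5, abs=1e-12)
            assert state.integral(opt) == pytest.approx(1.0, abs=1e-12)

    def test_small_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            bm.init_beliefs(2)

    def test_grid_refinement_stability(self):
        # the uniform prior's EV is grid-size independent; a one-update
        # posterior converges more slowly because the beta density has a
        # derivative singularity at theta = 1
        assert abs(bm.init_beliefs(200).mean("red") - bm.init_beliefs(400).mean("red")) < 1e-6
        ev = {}
        for K in (200, 400):
            state = bm.init_beliefs(K)
            new = bm.update_beliefs(state, "red", 1, bm.ModelParams(1.0, 1.0))
            ev[K] = new.mean("red")
        assert abs(ev[200] - ev[400]) < 1e-3

    def test_gainloss_likelihood_peaks_near_09(self):
        grid = np.linspace(0, 1, 10_001)
        dens = bm.likelihood_density(1, grid)
        assert round(grid[np.argmax(dens)], 1) == 0.9

    def test_nothing_likelihood_peaks_near_01(self):
        grid = np.linspace(0, 1, 10_001)
        dens = bm.likelihood_density(0, grid)
        assert round(grid[np.argmax(dens)], 1) == 0.1

    def test_density_vanishes_at_extremes(self):
        grid = np.linspace(0, 1, 101)
        for outcome in (1, -1, 0):
            dens = bm.likelihood_density(outcome, grid)
            assert dens[0] == 0.0 and dens[-1] == 0.0

    def test_grid_mean_matches_closed_form(self):
        # Beta(2, 1.1) mean = alpha / (alpha + beta)
        state = bm.init_beliefs(2001)
        d = bm.likelihood_density(1, state.grid)
        state.density[0] = d / (state._weights @ d)
        assert state.mean("red") == pytest.approx(2 / 3.1, abs=1e-4)


class TestUpdate:
    def test_gamma_zero_resets_to_uniform(self):
        state = bm.init_beliefs(101)
        state.density[0] = bm.likelihood_density(1, state.grid)
        state.density[0] /= state.integral("red")
        new = bm.update_beliefs(state, "red", 1, bm.ModelParams(0.0, 1.0))
        for opt in ("red", "blue"):
            assert np.allclose(new.density[new.option_index(opt)], 1.0, atol=1e-12)

    def test_full_retention_conjugate_posterior(self):
        state = bm.init_beliefs(2001)
        new = bm.update_beliefs(state, "red", 1, bm.ModelParams(1.0, 1.0))
        assert new.mean("red") == pytest.approx(2 / 3.1, abs=1e-4)

    def test_full_retention_leaves_nonchosen_unchanged(self):
        state = bm.init_beliefs(201)
        new = bm.update_beliefs(state, "red", 1, bm.ModelParams(1.0, 1.0))
        assert np.allclose(new.density[1], state.density[1])

    def test_unnormalized_state_rejected(self):
        state = bm.init_beliefs(201)
        state.density *= 3.0
        with pytest.raises(ValueError):
            bm.update_beliefs(state, "red", 1, bm.ModelParams(0.9, 1.0))

    def test_normalization_preserved_over_a_session(self, rng):
        state = bm.init_beliefs(201)
        params = bm.ModelParams(0.97, 0.1)
        for _ in range(360):
            chosen = "red" if rng.random() < 0.5 else "blue"
            outcome = int(rng.choice([1, 0, -1]))
            state = bm.update_beliefs(state, chosen, outcome, params)
            for opt in ("red", "blue"):
                assert abs(state.integral(opt) - 1.0) < 1e-9

    def test_repeated_gains_make_ev_nondecreasing(self):
        state = bm.init_beliefs(201)
        params = bm.ModelParams(1.0, 1.0)
        prev = bm.expected_value(state, "red", "gain")
        for _ in range(30):
            state = bm.update_beliefs(state, "red", 1, params)
            ev = bm.expected_value(state, "red", "gain")
            assert ev >= prev - 1e-12
            prev = ev

    def test_forgetting_keeps_interior_density_positive(self):
        state = bm.init_beliefs(201)
        params = bm.ModelParams(0.95, 1.0)
        for _ in range(100):
            state = bm.update_beliefs(state, "red", 1, params)
        assert np.all(state.density[:, 1:-1] > 0)


class TestChoiceRule:
    def test_equal_evs_give_half(self):
        for t in (0.01, 1.0, 10.0):
            assert bm.choice_probability(0.3, 0.3, t) == pytest.approx(0.5)

    def test_unit_temperature_value(self):
        assert bm.choice_probability(0.5, -0.5, 1.0) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-9
        )

    def test_greedy_limit(self):
        assert bm.choice_probability(0.5, -0.5, 0.01) == pytest.approx(1.0, abs=1e-9)

    def test_overflow_handled(self):
        p = bm.choice_probability(1e4, -1e4, 1.0)
        assert np.isfinite(p) and p == pytest.approx(1.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            bm.choice_probability(0.1, 0.2, 0.0)

    def test_complementarity(self):
        p = bm.choice_probability(0.4, -0.1, 0.3)
        q = bm.choice_probability(-0.1, 0.4, 0.3)
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestLatents:
    def test_uniform_beliefs_confidence_half(self):
        state = bm.init_beliefs(201)
        assert bm.confidence(state, "red", "blue") == pytest.approx(0.5, abs=1e-12)

    def test_confidence_beats_uniform_equals_its_mean(self):
        # P(X > U(0,1)) = E[X] for X independent of the uniform
        state = bm.init_beliefs(2001)
        d = bm.likelihood_density(1, state.grid)
        state.density[0] = d / (state._weights @ d)
        assert bm.confidence(state, "red", "blue") == pytest.approx(2 / 3.1, abs=1e-3)

    def test_confidence_complementarity(self, rng):
        state = bm.init_beliefs(201)
        state.density[0] = bm.likelihood_density(1, state.grid)
        state.density[0] /= state.integral("red")
        state.density[1] = bm.likelihood_density(0, state.grid)
        state.density[1] /= state.integral("blue")
        for block in ("gain", "loss"):
            total = bm.confidence(state, "red", "blue", block) + bm.confidence(
                state, "blue", "red", block
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_loss_block_reverses_confidence(self):
        state = bm.init_beliefs(201)
        state.density[0] = bm.likelihood_density(1, state.grid)
        state.density[0] /= state.integral("red")
        gain_conf = bm.confidence(state, "red", "blue", "gain")
        loss_conf = bm.confidence(state, "red", "blue", "loss")
        assert loss_conf == pytest.approx(1 - gain_conf, abs=1e-12)

    @pytest.mark.parametrize(
        "ev_a,ev_b,expected", [(0.5, 0.5, 0.5), (-0.5, -0.5, -0.5), (0.8, 0.2, 0.5)]
    )
    def test_context_value(self, ev_a, ev_b, expected):
        assert bm.context_value(ev_a, ev_b) == pytest.approx(expected)

    def test_expected_value_signs(self):
        state = bm.init_beliefs(201)
        assert bm.expected_value(state, "red", "gain") == pytest.approx(0.5)
        assert bm.expected_value(state, "red", "loss") == pytest.approx(-0.5)

    @pytest.mark.parametrize(
        "outcome,ev,pe", [(1, 0.5, 0.5), (0, 0.5, -0.5), (-1, -0.9, -0.1)]
    )
    def test_prediction_error(self, outcome, ev, pe):
        got_pe, got_abs = bm.prediction_error(outcome, ev)
        assert got_pe == pytest.approx(pe)
        assert got_abs == pytest.approx(abs(pe))

    def test_confidence_change_examples(self):
        assert bm.confidence_change(0.5, 0.7) == pytest.approx(0.2)
        assert bm.confidence_change(0.31, 0.31) == 0.0

    def test_gain_outcome_raises_confidence_of_chosen(self):
        state = bm.init_beliefs(201)
        pre = bm.confidence(state, "red", "blue")
        new = bm.update_beliefs(state, "red", 1, bm.ModelParams(1.0, 1.0))
        post = bm.confidence(new, "red", "blue")
        assert post > pre


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    gamma=st.floats(0.0, 1.0),
    outcome=st.sampled_from([1, 0, -1]),
    chosen=st.sampled_from(["red", "blue"]),
)
def test_update_preserves_normalization_property(gamma, outcome, chosen):
    state = bm.init_beliefs(101)
    new = bm.update_beliefs(state, chosen, outcome, bm.ModelParams(gamma, 1.0))
    for opt in ("red", "blue"):
        assert abs(new.integral(opt) - 1.0) < 1e-9
        assert np.all(new.density[new.option_index(opt)] >= 0)


class TestExtractLatents:
    def test_latent_table_invariants(self, rng):
        from mousebandit.synthetic_data import simulate_agent
        from mousebandit.task_env import TaskConfig

        trials = simulate_agent(TaskConfig(n_trials_per_block=40), bm.ModelParams(0.97, 0.1), rng)
        designs = [
            TrialDesign(r.block, r.trial_index, bool(r.is_exploitation), r.good_option,
                        r.position_red, bool(r.switched))
            for r in trials.itertuples()
        ]
        lat = bm.extract_latents(designs, list(trials["choice"]), list(trials["outcome"]),
                                 bm.ModelParams(0.97, 0.1))
        assert np.allclose(lat["abs_pe"], lat["pe"].abs())
        assert lat["confidence"].between(0, 1).all()
        gain = lat[lat["block"] == "gain"]
        loss = lat[lat["block"] == "loss"]
        assert gain["ev_chosen"].between(0, 1).all()
        assert loss["ev_chosen"].between(-1, 0).all()
        assert lat["confidence_change"].between(-1, 1).all()
        # learners should be confident more often than not
        assert lat["confidence"].mean() > 0.5
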