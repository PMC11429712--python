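"""Outcome-window responses and the dopamine regression."""

import numpy as np
import pandas as pd
import pytest

import policycomp as pc


def make_trace(time_ms, values):
    return pc.PhotometryTrace(time_ms=np.asarray(time_ms, dtype=float),
                              values=np.asarray(values, dtype=float),
                              sampling_rate=1000.0 / np.diff(time_ms)[0])


def uniform_grid():
    return np.arange(-200.0, 901.0, 10.0)


class TestWindowResponse:
    def test_constant_trace_cancels(self):
        t = uniform_grid()
        trace = make_trace(t, np.full((len(t), 3), 4.2))
        assert np.allclose(pc.window_response(trace), 0.0, atol=1e-12)

    def test_boxcar_difference(self):
        t = uniform_grid()
        vals = np.zeros((len(t), 2))
        vals[(t >= -100) & (t < 100)] = 1.5                  # baseline level
        vals[(t >= 300) & (t < 800)] = [3.5, 0.5]            # response level
        assert np.allclose(pc.window_response(make_trace(t, vals)),
                           [2.0, -1.0], atol=1e-12)

    def test_empty_window_errors(self):
        t = np.array([-200.0, 700.0, 1600.0])  # baseline window has no sample
        with pytest.raises(ValueError):
            pc.window_response(make_trace(t, np.zeros((3, 1))))


class TestZscoreWithinSession:
    def test_moments_per_session(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 5.0, 400)
        sess = np.repeat(["a", "b"], 200)
        z = pc.zscore_within_session(x, sess)
        for sid in "ab":
            m = sess == sid
            assert z[m].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[m].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        sess = np.repeat(["a", "b", "c"], 100)
        once = pc.zscore_within_session(x, sess)
        twice = pc.zscore_within_session(once, sess)
        assert np.allclose(once, twice, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        shape = rng.normal(size=100)
        x = np.concatenate([shape * 2 + 1, shape * 50 - 7])
        sess = np.repeat(["a", "b"], 100)
        z = pc.zscore_within_session(x, sess)
        assert np.allclose(z[:100], z[100:], atol=1e-10)

    def test_single_session_equals_global(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        z = pc.zscore_within_session(x, np.repeat("a", 100))
        assert np.allclose(z, (x - x.mean()) / x.std(ddof=1), atol=1e-12)

    def test_zero_variance_names_session(self):
        with pytest.raises(ValueError, match="flat"):
            pc.zscore_within_session(np.ones(10), np.repeat("flat", 10))


class TestBuildRegressors:
    def test_cost_column_zero_for_unconditioned_policy(self, task):
        tr = pc.generate_session(task, 0.0, 0.5, 500, seed=20)
        pol = pc.generating_policy(task, 0.0, 0.5)
        X = pc.build_regressors(tr, pol, pc.q_mean(task))
        assert np.allclose(X["cost"], 0.0, atol=1e-12)
        assert np.allclose(X["intercept"], 1.0)

    def test_outcome_matches_block_magnitudes(self, task):
        tr = pc.generate_session(task, 5.0, 0.5, 2000, seed=21)
        X = pc.build_regressors(tr, pc.estimate_policy(tr), pc.q_mean(task))
        hi = tr[(tr["block_type"] == "left-large") & tr["correct"]
                & (tr["contrast"] < 0)]
        assert set(X.loc[hi.index, "outcome"]) == {2.0}

    def test_mean_cost_equals_session_complexity(self, task):
        """Empirical mean of the cost column equals the session's plug-in
        complexity (in nats) when estimated without smoothing."""
        tr = pc.generate_session(task, 2.0, 0.6, 3000, seed=22)
        pol = pc.estimate_policy(tr, pseudocount=0)
        X = pc.build_regressors(tr, pol, pc.q_mean(task))
        assert X["cost"].mean() == pytest.approx(
            pc.mutual_information(pol) * np.log(2), abs=1e-12)


class TestFitDopamineRegression:
    def test_noiseless_generative_recovery(self, task):
        tr = pc.generate_session(task, 2.0, 0.65, 2000, seed=23)
        tr = pc.generate_responses(tr, task, noise_sd=0.0, seed=0)
        X = pd.DataFrame({"intercept": 1.0, "cost": tr["cost_true"],
                          "value": tr["value_true"], "outcome": tr["reward"]})
        fit = pc.fit_dopamine_regression(tr["response"].to_numpy(), X)
        assert np.allclose(fit.coef, [0.0, -1.0, -1.0, 1.0], atol=1e-8)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_matches_normal_equations(self, small_dataset):
        tr = small_dataset[0]
        pol = pc.estimate_policy(tr)
        q = pc.smooth_values(pc.empirical_q(tr), 0.25)
        X = pc.build_regressors(tr, pol, q)
        y = pc.zscore_within_session(tr["response"].to_numpy(),
                                     tr["session_id"].to_numpy())
        fit = pc.fit_dopamine_regression(y, X)
        Xm = X.to_numpy()
        beta_ne = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        assert np.allclose(fit.coef, beta_ne, atol=1e-8)
        # residuals orthogonal to every regressor (normal equations)
        assert np.all(np.abs(Xm.T @ fit.residuals) < 1e-8 * len(y))
        assert np.allclose(fit.tstats, fit.coef / fit.se)

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = pd.DataFrame({"intercept": 1.0, "cost": x, "value": 2 * x,
                          "outcome": rng.normal(size=50)})
        with pytest.raises(ValueError, match="collinear"):
            pc.fit_dopamine_regression(rng.normal(size=50), X)

    def test_permutation_breaks_effects(self, task):
        """Shuffling responses kills the non-intercept effects at the usual
        null rate (|t| < 2 in ~95% of permutations)."""
        tr = pc.generate_session(task, 2.0, 0.65, 2000, seed=24)
        tr = pc.generate_responses(tr, task, noise_sd=0.5, seed=24)
        pol = pc.estimate_policy(tr)
        X = pc.build_regressors(tr, pol, pc.smooth_values(pc.empirical_q(tr), 0.25))
        y = tr["response"].to_numpy().copy()
        rng = np.random.default_rng(25)
        below = []
        for _ in range(100):
            rng.shuffle(y)
            fit = pc.fit_dopamine_regression(y, X)
            below.append(np.abs(fit.tstats[1:]) < 2.0)
        assert np.all(np.mean(below, axis=0) >= 0.9)  # per-regressor null rate


class TestCompareCostModels:
    def test_generative_cost_favored(self, task):
        tr = pc.generate_session(task, 2.0, 0.65, 4000, seed=26)
        tr = pc.generate_responses(tr, task, noise_sd=0.5, seed=26)
        pol = pc.estimate_policy(tr)
        X = pc.build_regressors(tr, pol, pc.smooth_values(pc.empirical_q(tr), 0.25))
        y = pc.zscore_within_session(tr["response"].to_numpy(),
                                     tr["session_id"].to_numpy())
        assert pc.compare_cost_models(y, X) > 0

    def test_null_cost_not_favored(self, task):
        """Responses generated without any cost contribution, regressed on
        the true generative regressors: the penalty dominates and dBIC <= 0."""
        tr = pc.generate_session(task, 2.0, 0.65, 4000, seed=27)
        tr = pc.generate_responses(tr, task, noise_sd=0.5, seed=27)
        null_resp = (tr["response"] + tr["cost_true"]).to_numpy()  # remove cost
        X = pd.DataFrame({"intercept": 1.0, "cost": tr["cost_true"],
                          "value": tr["value_true"], "outcome": tr["reward"]})
        y = pc.zscore_within_session(null_resp, tr["session_id"].to_numpy())
        assert pc.compare_cost_models(y, X) <= 0


class TestPartialResiduals:
    def test_frisch_waugh_slope_identity(self, small_dataset):
        for tr in small_dataset[:3]:
            pol = pc.estimate_policy(tr)
            X = pc.build_regressors(tr, pol,
                                    pc.smooth_values(pc.empirical_q(tr), 0.25))
            y = pc.zscore_within_session(tr["response"].to_numpy(),
                                         tr["session_id"].to_numpy())
            fit = pc.fit_dopamine_regression(y, X)
            pr = pc.partial_residuals(fit, X, "cost")
            x = X["cost"].to_numpy()
            xc = np.column_stack([np.ones_like(x), x])
            slope = np.linalg.lstsq(xc, pr, rcond=None)[0][1]
            assert slope == pytest.approx(fit["cost"], abs=1e-8)

    def test_noiseless_partial_residual_is_pure_cost_term(self, task):
        tr = pc.generate_session(task, 2.0, 0.65, 1000, seed=28)
        tr = pc.generate_responses(tr, task, noise_sd=0.0, seed=0)
        X = pd.DataFrame({"intercept": 1.0, "cost": tr["cost_true"],
                          "value": tr["value_true"], "outcome": tr["reward"]})
        fit = pc.fit_dopamine_regression(tr["response"].to_numpy(), X)
        pr = pc.partial_residuals(fit, X, "cost")
        assert np.allclose(pr, fit["cost"] * tr["cost_true"], atol=1e-8)

    def test_binned_means_decrease_for_negative_cost_effect(self, task):
        tr = pc.generate_session(task, 3.0, 0.65, 8000, seed=29)
        tr = pc.generate_responses(tr, task, noise_sd=0.5, seed=29)
        pol = pc.estimate_policy(tr)
        X = pc.build_regressors(tr, pol, pc.smooth_values(pc.empirical_q(tr), 0.25))
        y = pc.zscore_within_session(tr["response"].to_numpy(),
                                     tr["session_id"].to_numpy())
        fit = pc.fit_dopamine_regression(y, X)
        assert fit["cost"] < 0
        pr = pc.partial_residuals(fit, X, "cost")
        # the cost regressor takes few distinct values per session, so use a
        # coarse median split rather than fine quantile bins
        hi = X["cost"] > X["cost"].median()
        assert pr[hi.to_numpy()].mean() < pr[~hi.to_numpy()].mean()

    def test_unknown_regressor(self, small_dataset):
        tr = small_dataset[0]
        pol = pc.estimate_policy(tr)
        X = pc.build_regressors(tr, pol, pc.empirical_q(tr))
        fit = pc.fit_dopamine_regression(tr["response"].to_numpy(), X)
        with pytest.raises(KeyError):
            pc.partial_residuals(fit, X, "nonesuch")


class TestCorrelateBetaOutcome:
    def test_identical_vectors(self):
        r, p = pc.correlate_beta_outcome([1.0, 2.0, 3.0, 4.0],
                                         [1.0, 2.0, 3.0, 4.0])
        assert r == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(30)
        hits = 0
        for _ in range(40):
            r, _ = pc.correlate_beta_outcome(rng.normal(size=55),
                                             rng.normal(size=55))
            hits += abs(r) < 0.27
        assert hits / 40 >= 0.9

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pc.correlate_beta_outcome([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_gain_modulated_sessions_positive(self, task):
        """Sessions whose response gain scales with beta yield r > 0."""
        ds = pc.generate_dataset(n_sessions=20, n_trials=400, seed=31,
                                 task=task, gain_by_beta=True)
        betas, coefs = [], []
        for tr in ds:
            pol = pc.estimate_policy(tr)
            X = pc.build_regressors(tr, pol,
                                    pc.smooth_values(pc.empirical_q(tr), 0.25))
            y = pc.zscore_within_session(tr["response"].to_numpy(),
                                         tr["session_id"].to_numpy())
            fit = pc.fit_dopamine_regression(y, X)
            betas.append(pc.fit_beta(tr, fill_q=pc.q_mean(task)).beta_hat)
            coefs.append(fit["outcome"])
        r, _ = pc.correlate_beta_outcome(betas, coefs)
        assert r > 0
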