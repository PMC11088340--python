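"""Signal/noise power, ASD fitting, the context-gain model, and
cross-validated predictive power."""

import numpy as np
import pytest

from amcoding import simulate as sim
from amcoding import stimuli as st
from amcoding import strf


class TestSignalNoisePower:
    def test_hand_computed_toy(self):
        pe = strf.signal_noise_power(np.array([[0.0, 2.0], [0.0, 4.0]]))
        assert pe.signal_power == pytest.approx(2.0)
        assert pe.noise_power == pytest.approx(0.5)
        assert pe.mean_total_power == pytest.approx(2.5)

    def test_identical_reps_have_zero_noise(self):
        r = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (4, 1))
        pe = strf.signal_noise_power(r)
        assert pe.noise_power == pytest.approx(0.0, abs=1e-12)
        assert pe.signal_power == pytest.approx(strf._power(r[0]))

    def test_additivity_identity_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n, t = rng.integers(2, 8), rng.integers(3, 50)
            r = rng.normal(size=(n, t)) * rng.uniform(0.1, 5)
            pe = strf.signal_noise_power(r)
            assert pe.signal_power + pe.noise_power == pytest.approx(
                pe.mean_total_power, abs=1e-12 * max(1, pe.mean_total_power)
            )

    def test_pure_noise_signal_power_near_zero(self):
        rng = np.random.default_rng(3)
        vals = [strf.signal_noise_power(rng.normal(size=(4, 100))).signal_power for _ in range(1000)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_single_rep_raises(self):
        with pytest.raises(ValueError):
            strf.signal_noise_power(np.zeros((1, 10)))

    @pytest.mark.parametrize(
        "signal, noise, expected",
        [(2.0, 0.5, True), (1.0, 0.5, True), (0.9, 0.5, False)],
    )
    def test_inclusion_rule(self, signal, noise, expected):
        pe = strf.PowerEstimates(signal, noise, signal + noise, 10)
        assert strf.include_unit(pe) is expected


class TestForwardModel:
    def test_zero_cgf_equals_simple_prediction(self, small_drc):
        rng = np.random.default_rng(0)
        s = st.scale_intensity(small_drc.level_matrix, "amp")
        prf = rng.normal(size=(6, s.shape[1]))
        cgf = np.zeros((4, 9))
        a = strf.context_model_predict(s, 0.3, prf, None)
        b = strf.context_model_predict(s, 0.3, prf, cgf)
        assert np.allclose(a, b)

    def test_context_field_shift_convention(self):
        s = np.zeros((6, 5))
        s[2, 2] = 1.0
        cgf = np.zeros((2, 3))
        cgf[1, 2] = 1.0  # tau = 1, phi = +1
        ctx = strf.context_field(s, cgf)
        # ctx(t, k) includes s(t-1, k+1): the tone at (2,2) contributes at (3,1)
        expected = np.zeros_like(s)
        expected[3, 1] = 1.0
        assert np.array_equal(ctx, expected)

    def test_homogeneous_poisson_baseline(self, small_drc):
        params = sim.LNPUnitParams(
            true_prf=np.zeros((4, small_drc.grid.n_freq)), true_cgf=None, c=0.1, scaling="amp"
        )
        counts, rate = sim.simulate_lnp_unit(params, small_drc, n_reps=4, seed=0)
        assert np.allclose(rate, 0.1)
        total = counts.size
        se = np.sqrt(0.1 / total)
        assert abs(counts.mean() - 0.1) < 3 * se


class TestASD:
    def test_noiseless_linear_response_recovered(self, small_drc):
        s = st.scale_intensity(small_drc.level_matrix, "amp")
        prf = sim.make_gabor_prf(8, s.shape[1], peak_weight=1.0, center_freq_bin=25)
        y = 0.5 + strf.apply_prf(s, prf)
        m = strf.fit_strf_asd(s, y, n_lags=8)
        r = np.corrcoef(m.prf.ravel(), prf.ravel())[0, 1]
        assert r > 0.999
        assert m.c == pytest.approx(0.5, abs=0.05)

    def test_poisson_recovery(self, small_drc, planted_lnp):
        params, counts, _ = planted_lnp
        m = strf.fit_strf_asd(small_drc, counts.mean(axis=0), scaling="amp", n_lags=8)
        r = np.corrcoef(m.prf.ravel(), params.true_prf.ravel())[0, 1]
        assert r >= 0.9

    def test_white_noise_response_is_shrunk(self, small_drc):
        rng = np.random.default_rng(4)
        s = st.scale_intensity(small_drc.level_matrix, "amp")[:2000]
        y = rng.normal(size=2000)
        m = strf.fit_strf_asd(s, y, n_lags=6)
        # unregularized least squares on the same design
        G, b, colsum, yty, ysum, n = strf._gram_and_xty(s, y, 6)
        Gc, bc, _, mu, ybar = strf._center(G, b, colsum, yty, ysum, n)
        w_ml = np.linalg.solve(Gc + 1e-8 * np.eye(Gc.shape[0]), bc)
        assert np.linalg.norm(m.prf) < np.linalg.norm(w_ml)

    def test_posterior_matches_ridge_in_short_length_limit(self):
        # with length scales -> 0 the SE prior becomes diagonal (ridge)
        rng = np.random.default_rng(6)
        s = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        n_lags = 2
        hyper = dict(log_rho=np.log(0.7), log_lt=np.log(1e-3), log_lf=np.log(1e-3), log_sig2=np.log(0.5))
        G, b, colsum, yty, ysum, n = strf._gram_and_xty(s, y, n_lags)
        Gc, bc, _, mu, ybar = strf._center(G, b, colsum, yty, ysum, n)
        prior = strf._ASDPrior(n_lags, 5)
        w = strf._solve_posterior(prior, hyper, Gc, bc)
        lam = 0.5 / 0.7  # sig2 / rho
        w_ridge = np.linalg.solve(Gc + lam * np.eye(Gc.shape[0]), bc)
        assert np.allclose(w, w_ridge, atol=1e-6)


class TestContextModel:
    def test_objective_monotone_and_sign_recovery(self, small_drc):
        prf = sim.make_gabor_prf(8, small_drc.grid.n_freq, center_freq_bin=30)
        cgf = sim.make_suppressive_cgf(5, 6)
        params = sim.LNPUnitParams(true_prf=prf, true_cgf=cgf, c=0.2, scaling="amp")
        counts, _ = sim.simulate_lnp_unit(params, small_drc, n_reps=10, seed=9)
        y = counts.mean(axis=0)
        base = strf.fit_strf_asd(small_drc, y, scaling="amp", n_lags=8)
        model = strf.fit_context_model(small_drc, y, scaling="amp", init=base, n_tau=5, n_phi=6, max_iter=10)
        obj = model.history["objective"]
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]))
        # suppressive weights along tau=0 and phi=0 recovered in sign
        assert model.cgf[0].mean() < 0
        assert model.cgf[:, 6].mean() < 0

    def test_cgf_free_unit_below_permutation_null(self, small_drc, planted_lnp):
        params, counts, _ = planted_lnp
        y = counts.mean(axis=0)
        base = strf.fit_strf_asd(small_drc, y, scaling="amp", n_lags=8)
        model = strf.fit_context_model(small_drc, y, scaling="amp", init=base, n_tau=5, n_phi=6, max_iter=10)
        null = strf.cgf_norm_null(small_drc, y, model, n_shifts=60, seed=1)
        assert np.linalg.norm(model.cgf) < np.quantile(null, 0.95)


class TestPredictivePower:
    def test_perfect_prediction_scores_one(self):
        rng = np.random.default_rng(8)
        r = rng.normal(size=500)
        pe_signal = strf._power(r)
        assert strf._normalized_pp(r, r.copy(), pe_signal) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self):
        rng = np.random.default_rng(9)
        r = rng.normal(size=500)
        rho = np.full(500, r.mean())
        assert strf._normalized_pp(r, rho, strf._power(r)) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_repetition_relabeling(self, small_drc, planted_lnp):
        _, counts, _ = planted_lnp
        perm = np.random.default_rng(0).permutation(counts.shape[0])
        a = strf.cv_predictive_power("simple", small_drc, counts, folds=5, reps=1, seed=3, n_lags=8, maxfun=30)
        b = strf.cv_predictive_power("simple", small_drc, counts[perm], folds=5, reps=1, seed=3, n_lags=8, maxfun=30)
        assert a.predictive_power_norm == pytest.approx(b.predictive_power_norm, abs=1e-9)

    def test_simple_model_explains_planted_linear_unit(self, small_drc, planted_lnp):
        _, counts, _ = planted_lnp
        score = strf.cv_predictive_power("simple", small_drc, counts, folds=10, reps=1, seed=0, n_lags=8)
        assert 0.5 < score.predictive_power_norm <= 1.1


class TestMetrics:
    def test_self_comparison(self, small_drc, planted_lnp):
        params, counts, _ = planted_lnp
        m = strf.fit_strf_asd(small_drc, counts.mean(axis=0), scaling="amp", n_lags=8)
        out = strf.strf_metrics(m, m, freqs=small_drc.grid.frequencies)
        assert out["prf_correlation"] == pytest.approx(1.0)
        assert out["delta_bf_oct"] == 0.0
        # planted center frequency bin 30 recovered within one bin (1/12 oct)
        assert abs(out["bf_bin"] - 30) <= 1

    def test_negated_model_anticorrelates(self, small_drc, planted_lnp):
        params, counts, _ = planted_lnp
        m = strf.fit_strf_asd(small_drc, counts.mean(axis=0), scaling="amp", n_lags=8)
        neg = strf.STRFModel(c=-m.c, prf=-m.prf)
        out = strf.strf_metrics(m, neg)
        assert out["prf_correlation"] == pytest.approx(-1.0)
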