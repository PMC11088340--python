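"""Vector strength, VS_PP, ROC/d', and modulation-depth thresholds."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import norm

from amcoding import amcode
from amcoding.amcode import SpikeTrain


def brute_force_auc(signal, null):
    wins = sum(1.0 if s > n else 0.5 if s == n else 0.0 for s in signal for n in null)
    return wins / (len(signal) * len(null))


class TestVectorStrength:
    def test_identical_phases(self):
        vs, mp = amcode.vector_strength(np.full(5, 1.2))
        assert vs == pytest.approx(1.0)
        assert mp == pytest.approx(1.2)

    def test_symmetric_phases_cancel(self):
        vs, _ = amcode.vector_strength([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert vs == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_complex_sum(self):
        vs, mp = amcode.vector_strength([0.0, 0.0, np.pi / 2])
        assert vs == pytest.approx(np.sqrt(5) / 3)
        assert mp == pytest.approx(np.arctan2(1, 2))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            amcode.vector_strength([])


class TestVSPP:
    def _train(self, times, depth=1.0):
        return SpikeTrain(np.asarray(times, float), fmod=10.0, depth=depth, intensity=60.0)

    def test_perfect_common_locking(self):
        # spikes at the same modulation phase on every trial
        trials = [self._train(0.025 + np.arange(5) / 10.0) for _ in range(4)]
        per_trial, mean = amcode.vs_pp(trials, fmod=10.0, window=(0.0, 0.5))
        assert np.allclose(per_trial, 1.0)
        assert mean == pytest.approx(1.0)

    def test_antiphase_trial_contributes_minus_one(self):
        good = [self._train(0.0 + np.arange(10) / 10.0) for _ in range(10)]
        bad = [self._train(0.05 + np.arange(1) / 10.0)]
        per_trial, _ = amcode.vs_pp(good + bad, fmod=10.0, window=(0.0, 1.0))
        assert per_trial[-1] == pytest.approx(-1.0, abs=0.01)

    def test_zero_spike_trial_contributes_zero(self):
        trials = [self._train([0.025]), self._train([])]
        per_trial, _ = amcode.vs_pp(trials, fmod=10.0, window=(0.0, 0.5))
        assert per_trial[1] == 0.0

    def test_poisson_null_centered_on_zero(self):
        rng = np.random.default_rng(2)
        trials = [self._train(np.sort(rng.uniform(0, 1, size=100))) for _ in range(100)]
        per_trial, mean = amcode.vs_pp(trials, fmod=64.0, window=(0.0, 1.0))
        se = per_trial.std(ddof=1) / np.sqrt(per_trial.size)
        assert abs(mean) < 3 * se + 1e-12
        assert np.all(np.abs(per_trial) <= 1.0)


class TestROC:
    def test_identical_lists(self):
        assert amcode.roc_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_fully_separated(self):
        assert amcode.roc_auc([4, 5], [1, 2]) == 1.0

    def test_hand_counted_ties(self):
        assert amcode.roc_auc([1, 2, 3], [2, 2]) == pytest.approx(0.5)

    def test_exhaustive_pair_counting_oracle(self):
        # all multisets of sizes 1..4 over {0, 1, 2} (AUC is order-invariant)
        lists = [
            list(c)
            for n in range(1, 5)
            for c in itertools.combinations_with_replacement([0, 1, 2], n)
        ]
        for s in lists:
            for nl in lists:
                assert amcode.roc_auc(s, nl) == pytest.approx(brute_force_auc(s, nl), abs=1e-12)

    @given(
        hst.lists(hst.integers(0, 2), min_size=1, max_size=6),
        hst.lists(hst.integers(0, 2), min_size=1, max_size=6),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_complement_identity(self, a, b):
        assert amcode.roc_auc(a, b) + amcode.roc_auc(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            amcode.roc_auc([], [1])


class TestDprime:
    @pytest.mark.parametrize(
        "auc, expected",
        [(0.5, 0.0), (norm.cdf(1 / np.sqrt(2)), 1.0), (norm.cdf(np.sqrt(2)), 2.0)],
    )
    def test_sqrt2_convention(self, auc, expected):
        assert amcode.dprime_from_auc(auc) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_alternative_convention(self):
        a = 0.8
        assert amcode.dprime_from_auc(a) == pytest.approx(amcode.dprime_from_auc(1 - a))
        assert amcode.dprime_from_auc(a, convention="2") == pytest.approx(
            np.sqrt(2) * amcode.dprime_from_auc(a)
        )

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            amcode.dprime_from_auc(1.2)


class TestThreshold:
    def test_hand_interpolated_crossing(self):
        thr = amcode.modulation_threshold([-12.04, -6.02], [0.5, 1.5])
        assert thr.threshold_db == pytest.approx(-9.03)
        assert not thr.censored

    def test_never_reaching_one_is_undefined(self):
        thr = amcode.modulation_threshold([-18.0, -12.0, -6.0], [0.2, 0.5, 0.9])
        assert not thr.defined

    def test_exact_touch_and_censoring(self):
        thr = amcode.modulation_threshold([-18.06, -12.04], [1.0, 2.0])
        assert thr.threshold_db == pytest.approx(-18.06)
        assert not thr.censored
        thr2 = amcode.modulation_threshold([-18.06, -12.04], [1.5, 2.0])
        assert thr2.threshold_db == pytest.approx(-18.06)
        assert thr2.censored

    def test_scaling_never_raises_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 7)
            depths = np.sort(rng.uniform(-30, 0, size=n))
            while np.any(np.diff(depths) <= 0):
                depths = np.sort(rng.uniform(-30, 0, size=n))
            d = rng.uniform(0, 2.5, size=n)
            k = rng.uniform(1.0, 4.0)
            t1 = amcode.modulation_threshold(depths, d)
            t2 = amcode.modulation_threshold(depths, k * d)
            if t1.defined:
                assert t2.defined
                assert t2.threshold_db <= t1.threshold_db + 1e-9

    def test_invariant_to_depths_above_crossing(self):
        base = amcode.modulation_threshold([-20.0, -10.0], [0.5, 1.5])
        extended = amcode.modulation_threshold([-20.0, -10.0, -5.0, 0.0], [0.5, 1.5, 2.0, 3.0])
        assert extended.threshold_db == pytest.approx(base.threshold_db)

    def test_nonmonotone_grid_raises(self):
        with pytest.raises(ValueError):
            amcode.modulation_threshold([-6.0, -12.0], [0.5, 1.5])


class TestSensitivityCurve:
    def test_strong_locker_monotone_dprime_and_threshold(self, locked_unit_trains):
        curve = amcode.sensitivity_curve(locked_unit_trains, "temporal", 16.0, (1.5, 2.0))
        assert curve.dprime[-1] > 1.0
        # d' rises with depth overall (allow small local noise)
        assert curve.dprime[-1] == max(curve.dprime)
        assert curve.threshold.defined

    def test_rate_coding_uses_depth_gain(self, locked_unit_trains):
        curve = amcode.sensitivity_curve(locked_unit_trains, "rate", 16.0, (1.5, 2.0))
        assert curve.dprime[-1] > 1.0

    def test_non_locking_unit_flat(self, sam_grid_16hz):
        from amcoding import simulate as sim

        up = sim.SAMUnitParams(r_base=20.0, lock_strength=0.0, gain={})
        trains = sim.simulate_sam_unit(up, sam_grid_16hz, n_trials=20, seed=3)
        by_depth = {}
        for tr in trains:
            by_depth.setdefault(tr.depth, []).append(tr)
        curve = amcode.sensitivity_curve(by_depth, "temporal", 16.0, (1.5, 2.0))
        assert np.all(curve.dprime < 1.0)
        assert not curve.threshold.defined

    def test_missing_null_raises(self, locked_unit_trains):
        partial = {d: v for d, v in locked_unit_trains.items() if d > 0}
        with pytest.raises(ValueError):
            amcode.sensitivity_curve(partial, "temporal", 16.0, (1.5, 2.0))
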