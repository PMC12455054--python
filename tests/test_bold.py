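"""Normalization, group time courses, pointwise testing, recovery, subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nadbold as nb
from nadbold.bold import (GroupTimecourse, RecoveryConfig, group_timecourse,
                          normalize, pointwise_difference_test, recovery_time,
                          subtract_condition)
from nadbold.io import BoldSeries, ValidationError


def _series(values, tr=2.0, stim=None):
    return BoldSeries(values=np.asarray(values, float), tr=tr, stim_volume=stim)


def _tc(mean, stim=960, tr=2.0):
    mean = np.asarray(mean, float)
    return GroupTimecourse(mean=mean, sd=np.zeros_like(mean), n=5, tr=tr,
                           stim_volume=stim)


class TestNormalize:
    def test_constant_series(self):
        out = normalize(_series(np.full(10, 3.7)))
        np.testing.assert_allclose(out.values, 100.0)

    def test_hand_computation(self):
        np.testing.assert_allclose(normalize(_series([1, 2, 3])).values,
                                   [50, 100, 150])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        x = np.array([90.0, 100.0, 110.0, 105.0])
        a = normalize(_series(x)).values
        b = normalize(_series(c * x)).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_mean_is_100_to_1e9_relative(self, rng):
        out = normalize(_series(rng.normal(1200, 40, 3660)))
        assert abs(out.values.mean() - 100.0) < 100.0 * 1e-9

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            normalize(_series([-1.0, -2.0]))


class TestGroupTimecourse:
    def test_identical_inputs_sd_zero(self):
        s = normalize(_series([100, 101, 99]))
        tc = group_timecourse([s, s, s])
        np.testing.assert_allclose(tc.sd, 0.0)
        assert tc.n == 3

    def test_two_series_hand_computation(self):
        a = nb.bold.NormalizedSeries(values=np.array([98.0]), tr=2.0)
        b = nb.bold.NormalizedSeries(values=np.array([102.0]), tr=2.0)
        tc = group_timecourse([a, b])
        assert tc.mean[0] == 100.0
        assert tc.sd[0] == pytest.approx(2 * np.sqrt(2))

    def test_length_mismatch_rejected(self):
        a = nb.bold.NormalizedSeries(values=np.zeros(5), tr=2.0)
        b = nb.bold.NormalizedSeries(values=np.zeros(6), tr=2.0)
        with pytest.raises(ValidationError):
            group_timecourse([a, b])


class TestPointwiseTest:
    def test_identical_groups_empty_mask(self, rng):
        g = rng.normal(100, 1, size=(4, 200))
        mask, p = pointwise_difference_test(g, g.copy())
        assert not mask.any()
        np.testing.assert_allclose(p, 1.0)  # zero pooled variance convention

    def test_planted_difference_recovered_exactly(self, rng):
        n_vol = 1000
        base = np.zeros((5, n_vol))
        a = base.copy()
        b = base.copy()
        a[:, 100:200] += 10.0 + rng.normal(0, 0.01, size=(5, 100))
        b[:, 100:200] += rng.normal(0, 0.01, size=(5, 100))
        mask, _ = pointwise_difference_test(a, b, alpha=0.01)
        np.testing.assert_array_equal(np.nonzero(mask)[0], np.arange(100, 200))

    def test_matches_scipy_per_volume(self, rng):
        from scipy import stats as sps
        a = rng.normal(100, 1, size=(5, 50))
        b = rng.normal(100.5, 1, size=(6, 50))
        _, p = pointwise_difference_test(a, b)
        expect = sps.ttest_ind(a, b, axis=0, equal_var=True).pvalue
        np.testing.assert_allclose(p, expect, rtol=1e-10)

    def test_symmetry_and_shift_invariance(self, rng):
        a = rng.normal(0, 1, size=(5, 40))
        b = rng.normal(1, 1, size=(5, 40))
        m1, p1 = pointwise_difference_test(a, b)
        m2, p2 = pointwise_difference_test(b, a)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)
        _, p3 = pointwise_difference_test(a + 5.0, b + 5.0)
        np.testing.assert_allclose(p1, p3, rtol=1e-9)

    def test_drift_regimes_diverge_after_30_minutes(self):
        """Isoflurane rises, medetomidine declines after minute 30: against the
        pre-drug baseline the conditions separate tens of minutes in."""
        iso, med = [], []
        root = np.random.SeedSequence(77)
        for child in root.spawn(10):
            rng = np.random.default_rng(child)
            scale = max(float(rng.normal(1.0, 0.1)), 0.0)
            d_iso = nb.SessionDesign(stimulated=False, seed=1)
            s, _ = nb.generate_bold(d_iso, nb.BoldTruth(
                drift_model="isoflurane", drift_scale=scale), rng)
            iso.append(s.values)
            d_med = nb.SessionDesign(anesthetic="medetomidine",
                                     stimulated=False, seed=1)
            s, _ = nb.generate_bold(d_med, nb.BoldTruth(
                drift_model="medetomidine", drift_scale=scale,
                wave_rate=3.0), rng)
            med.append(s.values)
        mask, _ = pointwise_difference_test(np.vstack(iso[:5]), np.vstack(med[5:]))
        # sporadic single-volume crossings aside, sustained divergence (half
        # of a 5-min window significant) begins tens of minutes in
        assert mask[:600].mean() < 0.05          # rare before minute 20
        rolling = np.convolve(mask.astype(float), np.ones(150) / 150, "valid")
        onset_min = np.nonzero(rolling >= 0.5)[0][0] * 2.0 / 60.0
        assert 20.0 <= onset_min <= 60.0
        assert mask[1500:].mean() > 0.9          # dominant after minute 50


def oracle_recovery(mean, stim, cfg=RecoveryConfig()):
    b0, b1 = cfg.baseline_volumes
    thr = cfg.threshold_fraction * mean[b0:b1 + 1].mean()
    P = cfg.persistence_volumes
    for v in range(stim, mean.size - P + 1):
        if bool((mean[v:v + P] >= thr).all()):
            return v
    return None


class TestRecoveryTime:
    def _flat_series(self, level_after=100.0, n=3660):
        x = np.full(n, 100.0)
        x[960:] = level_after
        return x

    def test_never_declined_recovers_immediately(self):
        res = recovery_time(_tc(np.full(3660, 100.0)))
        assert res.recovered and res.recovery_minutes == 0.0

    def test_linear_return_crossing_at_41_minutes(self):
        x = np.full(3660, 100.0)
        k = np.arange(3660 - 960)
        # drop to 96%, linear return crossing 98% exactly at volume 960+1230
        x[960:] = 96.0 + 2.0 * k / 1230.0
        res = recovery_time(_tc(x))
        assert res.recovered
        assert res.recovery_minutes == pytest.approx(41.0, abs=0.04)

    def test_sustained_shortfall_is_censored(self):
        res = recovery_time(_tc(self._flat_series(97.0)))
        assert not res.recovered
        assert res.recovery_minutes is None
        assert res.censor_time == pytest.approx(90.0)

    def test_single_volume_blip_does_not_count(self):
        x = self._flat_series(97.0)
        x[2000] = 100.0
        res = recovery_time(_tc(x))
        assert not res.recovered

    def test_equals_bruteforce_oracle(self, rng):
        for _ in range(10):
            x = 100.0 + rng.normal(0, 1.5, 3660)
            tc = _tc(x)
            res = recovery_time(tc)
            v = oracle_recovery(x, 960)
            if v is None:
                assert not res.recovered
            else:
                assert res.recovered
                assert res.recovery_minutes == pytest.approx((v - 960) * 2 / 60)

    def test_baseline_after_stim_rejected(self):
        with pytest.raises(ValidationError):
            recovery_time(_tc(np.full(3660, 100.0), stim=900))


class TestSubtractCondition:
    def test_self_subtraction_is_flat_100(self, rng):
        t = GroupTimecourse(mean=rng.normal(100, 2, 100), sd=rng.random(100),
                            n=5, tr=2.0)
        out = subtract_condition(t, t)
        np.testing.assert_allclose(out.mean, 100.0)

    def test_hand_computation(self):
        t = _tc([95.0] * 10, stim=None)
        c = _tc([98.0] * 10, stim=None)
        np.testing.assert_allclose(subtract_condition(t, c).mean, 97.0)

    def test_roundtrip_recovers_target(self, rng):
        t = GroupTimecourse(mean=rng.normal(100, 2, 50), sd=np.ones(50), n=5, tr=2.0)
        c = GroupTimecourse(mean=rng.normal(100, 2, 50), sd=np.ones(50), n=5, tr=2.0)
        out = subtract_condition(t, c)
        np.testing.assert_allclose(out.mean + control_anchor(c), t.mean, rtol=1e-12)

    def test_sd_quadrature(self):
        t = GroupTimecourse(mean=np.zeros(3), sd=np.full(3, 3.0), n=5, tr=2.0)
        c = GroupTimecourse(mean=np.zeros(3), sd=np.full(3, 4.0), n=5, tr=2.0)
        np.testing.assert_allclose(subtract_condition(t, c).sd, 5.0)


def control_anchor(control):
    return control.mean - 100.0
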