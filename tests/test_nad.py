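"""Afterdischarge end detection, per-second AUC intensity and group summaries."""

import numpy as np
import pytest

import nadbold as nb
from nadbold.ephys import BaselineStats
from nadbold.io import LfpRecording, ValidationError
from nadbold.nad import (NadDetectorConfig, detect_nad_end, envelope,
                         nad_intensity, summarize_group)

FS = 1000.0


def _trace(x, **kw):
    return LfpRecording(samples=np.asarray(x, float), sample_rate=FS, **kw)


def _baseline(amp=0.05):
    return BaselineStats(mean_abs_amplitude=amp, window=(0.0, 60.0),
                         n_samples_used=60000)


def oracle_nad_end(trace, stim_end, baseline, cfg=NadDetectorConfig()):
    """Sample-by-sample scan: earliest index whose full persistence window sits
    below threshold. Independent of the production implementation."""
    thr = cfg.threshold_factor * baseline.mean_abs_amplitude
    env = envelope(trace.samples, trace.sample_rate, cfg.envelope_window)
    P = int(round(cfg.persistence * trace.sample_rate))
    i0 = max(trace.index_at(stim_end), 0)
    i1 = min(trace.index_at(stim_end + cfg.max_search), trace.samples.size)
    for i in range(i0, i1):
        if i + P > env.size:
            break
        if bool((env[i:i + P] < thr).all()):
            return trace.t0 + i / trace.sample_rate, False
    return stim_end + cfg.max_search, True


def _square_burst(duration, level, total=30.0, stim_end=5.0):
    """|x| = level between stim_end and stim_end + duration, tiny elsewhere."""
    n = int(total * FS)
    x = np.full(n, 1e-4)
    i0, i1 = int(stim_end * FS), int((stim_end + duration) * FS)
    x[i0:i1] = level
    x[::2] *= -1
    return _trace(x)


class TestDetectNadEnd:
    def test_silent_trace_gives_zero_duration(self):
        ev = detect_nad_end(_trace(np.zeros(30000)), 5.0, _baseline())
        assert ev.duration == 0.0
        assert not ev.censored

    def test_square_burst_duration_within_envelope_window(self):
        tr = _square_burst(10.0, level=0.5)  # 10x the 0.05 baseline
        ev = detect_nad_end(tr, 5.0, _baseline())
        assert ev.duration == pytest.approx(10.0, abs=0.1 + 1 / FS)

    @pytest.mark.parametrize("duration", [0.0, 1.5, 7.3, 10.0, 24.9])
    def test_equals_bruteforce_oracle(self, duration):
        tr = _square_burst(duration, level=0.5)
        ev = detect_nad_end(tr, 5.0, _baseline())
        end, censored = oracle_nad_end(tr, 5.0, _baseline())
        assert ev.nad_end == end
        assert ev.censored == censored

    def test_oracle_agreement_on_synthetic_session(self, session_10s):
        cond, d = session_10s["conditioned"], session_10s["design"]
        base = session_10s["baseline"]
        ev = detect_nad_end(cond, d.train_end, base)
        end, censored = oracle_nad_end(cond, d.train_end, base)
        assert ev.nad_end == end and ev.censored == censored

    def test_brief_dip_does_not_terminate(self):
        # 0.5 s quiet dip inside the burst: shorter than the 1-s persistence
        tr = _square_burst(12.0, level=0.5)
        tr.samples[int(9.0 * FS):int(9.5 * FS)] = 1e-4
        ev = detect_nad_end(tr, 5.0, _baseline())
        assert ev.duration == pytest.approx(12.0, abs=0.2)

    def test_long_dip_terminates(self):
        tr = _square_burst(12.0, level=0.5)
        tr.samples[int(9.0 * FS):int(10.5 * FS)] = 1e-4  # 1.5 s > persistence
        ev = detect_nad_end(tr, 5.0, _baseline())
        assert ev.duration == pytest.approx(4.0, abs=0.2)

    def test_censoring_when_activity_never_stops(self):
        tr = _square_burst(25.0, level=0.5, total=30.0)
        cfg = NadDetectorConfig(max_search=15.0)
        ev = detect_nad_end(tr, 5.0, _baseline(), cfg)
        assert ev.censored
        assert ev.duration == 15.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            detect_nad_end(_trace(np.zeros(10000)), 5.0, _baseline(0.0))

    def test_threshold_monotonicity(self):
        # raising the threshold factor can only shorten the detected event
        tr = _square_burst(10.0, level=0.5)
        durations = [detect_nad_end(tr, 5.0, _baseline(),
                                    NadDetectorConfig(threshold_factor=f)).duration
                     for f in (2.0, 5.0, 8.0)]
        assert durations == sorted(durations, reverse=True)


class TestNadIntensity:
    def test_zero_trace(self):
        ev = nb.NadEvent(stim_end=5.0, nad_end=8.0)
        ev = nad_intensity(_trace(np.zeros(20000)), ev)
        assert ev.auc_per_second == [0.0, 0.0, 0.0]
        assert ev.total_auc == 0.0

    def test_unit_rectified_trace(self):
        x = np.tile([1.0, -1.0], 10000)
        ev = nad_intensity(_trace(x), nb.NadEvent(stim_end=5.0, nad_end=8.0))
        np.testing.assert_allclose(ev.auc_per_second, [1.0, 1.0, 1.0], rtol=1e-9)

    def test_partial_final_bin_prorata(self):
        x = np.tile([1.0, -1.0], 10000)
        ev = nad_intensity(_trace(x), nb.NadEvent(stim_end=5.0, nad_end=7.5))
        np.testing.assert_allclose(ev.auc_per_second, [1.0, 1.0, 0.5], rtol=1e-9)
        assert ev.total_auc == pytest.approx(sum(ev.auc_per_second))

    def test_amplitude_linearity(self, rng):
        x = rng.standard_normal(20000)
        e1 = nad_intensity(_trace(x), nb.NadEvent(stim_end=5.0, nad_end=9.0))
        e2 = nad_intensity(_trace(2 * x), nb.NadEvent(stim_end=5.0, nad_end=9.0))
        np.testing.assert_allclose(e2.auc_per_second,
                                   [2 * a for a in e1.auc_per_second], rtol=1e-12)
        assert e2.total_auc == pytest.approx(2 * e1.total_auc, rel=1e-12)


class TestSummarizeGroup:
    def test_equal_values(self):
        s = summarize_group([13.25, 13.25])
        assert (s.mean, s.sd, s.n) == (13.25, 0.0, 2)

    def test_hand_computation(self):
        s = summarize_group([1, 2, 3])
        assert s.mean == 2.0
        assert s.sd == 1.0

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            summarize_group([13.0])

    def test_cohort_regime_mean(self):
        """Five sessions drawn in the medetomidine regime: detected durations
        summarize near the drawn truths."""
        drawn, detected = [], []
        rng = np.random.default_rng(5)
        for k in range(5):
            mu, sd = nb.synth.NAD_DURATION_REGIMES["med"]
            d = float(np.clip(rng.normal(mu, sd), 3, None))
            design = nb.SessionDesign(anesthetic="medetomidine", seed=900 + k)
            rec, _ = nb.generate_lfp(design, nb.LfpTruth(nad_duration=d))
            cond = nb.condition(rec)
            base = nb.baseline_amplitude(cond, design.stim_onset)
            detected.append(detect_nad_end(cond, design.train_end, base).duration)
            drawn.append(d)
        s_det, s_true = summarize_group(detected), summarize_group(drawn)
        assert s_det.mean == pytest.approx(s_true.mean, abs=0.5)
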