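"""Conditioning of raw LFP recorded inside the scanner.

Raw traces are sampled at 5000 Hz and carry two families of artifacts:
biphasic stimulation artifacts at each electrical pulse and gradient
artifacts at every volume trigger (one per TR). The conditioning chain is

    blank artifacts -> downsample to 1000 Hz -> zero-phase 0.5-100 Hz band-pass

after which afterdischarge detection operates on the trace. Blanking happens
before filtering so that the large transients cannot ring through the 100 Hz
low-pass; the band filter is a 4th-order Butterworth applied forward-backward
(zero phase), so event latencies are not biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import LfpRecording, ValidationError

__all__ = [
    "ConditioningConfig",
    "BaselineStats",
    "blank_artifacts",
    "downsample",
    "band_filter",
    "baseline_amplitude",
    "condition",
]


@dataclass(frozen=True)
class ConditioningConfig:
    """Parameters of the conditioning chain.

    ``blank_window_stim`` / ``blank_window_gradient`` are half-widths in
    seconds around each stimulation pulse / volume trigger; ``baseline_window``
    is the length of pre-stimulation trace used for the ongoing-activity
    estimate.
    """

    target_rate: float = 1000.0
    hp_cutoff: float = 0.5
    lp_cutoff: float = 100.0
    blank_window_stim: float = 0.005
    blank_window_gradient: float = 0.010
    baseline_window: float = 60.0

    def __post_init__(self):
        if not (0 < self.hp_cutoff < self.lp_cutoff < self.target_rate / 2):
            raise ValidationError("require 0 < hp_cutoff < lp_cutoff < target_rate/2")
        if min(self.blank_window_stim, self.blank_window_gradient,
               self.baseline_window) < 0:
            raise ValidationError("windows must be non-negative")


@dataclass(frozen=True)
class BaselineStats:
    """Mean absolute amplitude of ongoing activity in a pre-stimulation window."""

    mean_abs_amplitude: float
    window: tuple
    n_samples_used: int

    def __post_init__(self):
        if self.mean_abs_amplitude < 0:
            raise ValidationError("mean_abs_amplitude must be >= 0")


def _merge_intervals(intervals):
    """Merge overlapping/touching (start, end) intervals."""
    if not intervals:
        return []
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(iv) for iv in out]


def blank_artifacts(rec: LfpRecording, cfg: ConditioningConfig = ConditioningConfig()
                    ) -> LfpRecording:
    """Replace samples around stimulation pulses and volume triggers.

    Each window is replaced by linear interpolation between the samples at its
    edges; overlapping windows are merged first so no stretch is interpolated
    twice. Blanking is idempotent: interpolated segments are already linear,
    so re-blanking reproduces them exactly. The blanked intervals are recorded
    on the output so later amplitude statistics can exclude them.
    """
    intervals = [(t - cfg.blank_window_stim, t + cfg.blank_window_stim)
                 for t in rec.stim_pulses]
    intervals += [(t - cfg.blank_window_gradient, t + cfg.blank_window_gradient)
                  for t in rec.volume_triggers]
    intervals = _merge_intervals(intervals)
    x = rec.samples.copy()
    n = x.size
    blanked = 0
    kept: list = []
    for a, b in intervals:
        i0 = max(rec.index_at(a), 0)
        i1 = min(int(np.floor((b - rec.t0) * rec.sample_rate + 1e-9)) + 1, n)
        if i1 <= i0:
            continue
        lo = max(i0 - 1, 0)
        hi = min(i1, n - 1)
        x[i0:i1] = np.interp(np.arange(i0, i1), [lo, hi], [x[lo], x[hi]])
        blanked += i1 - i0
        kept.append((a, b))
    out = rec.copy_with(samples=x)
    out.blank_intervals = _merge_intervals(list(rec.blank_intervals) + kept)
    out.processing = list(rec.processing) + ["blank_artifacts"]
    out.meta = {**rec.meta, "n_blanked_samples": blanked}
    return out


def downsample(rec: LfpRecording, target_rate: float = 1000.0) -> LfpRecording:
    """Decimate to ``target_rate`` with an anti-alias FIR low-pass.

    The raw rate must be an integer multiple of the target (5000 -> 1000,
    factor 5). Event times are in seconds and carry over unchanged; the
    duration is preserved to within one output sample.
    """
    ratio = rec.sample_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValidationError(
            f"sample_rate {rec.sample_rate} not an integer multiple of {target_rate}")
    if factor == 1:
        return rec
    y = signal.decimate(rec.samples, factor, ftype="fir", zero_phase=True)
    out = rec.copy_with(samples=y, sample_rate=target_rate)
    out.processing = list(rec.processing) + [f"downsample:{factor}"]
    return out


def band_filter(rec: LfpRecording, cfg: ConditioningConfig = ConditioningConfig()
                ) -> LfpRecording:
    """Zero-phase Butterworth band-pass (default 0.5-100 Hz).

    The trace mean is removed before filtering; the high-pass corner then
    keeps the output mean at ~0. Refuses traces shorter than three times the
    high-pass time constant (the filter warm-up) and refuses to filter twice.
    """
    if any(step.startswith("band_filter") for step in rec.processing):
        raise ValidationError("trace already band-filtered")
    if abs(rec.sample_rate - cfg.target_rate) > 1e-9:
        raise ValidationError(
            f"band_filter expects the target rate {cfg.target_rate} Hz; downsample first")
    warmup = 3.0 / (2 * np.pi * cfg.hp_cutoff)
    if rec.duration < warmup:
        raise ValidationError(
            f"trace ({rec.duration:.3g} s) shorter than filter warm-up ({warmup:.3g} s)")
    sos = signal.butter(4, [cfg.hp_cutoff, cfg.lp_cutoff], btype="bandpass",
                        fs=rec.sample_rate, output="sos")
    y = signal.sosfiltfilt(sos, rec.samples - rec.samples.mean())
    out = rec.copy_with(samples=y)
    out.processing = list(rec.processing) + [
        f"band_filter:{cfg.hp_cutoff}-{cfg.lp_cutoff}"]
    return out


def baseline_amplitude(rec: LfpRecording, stim_onset: float,
                       cfg: ConditioningConfig = ConditioningConfig()) -> BaselineStats:
    """Mean |amplitude| of ongoing activity in the window before stimulation.

    The window is ``[stim_onset - baseline_window, stim_onset)``; samples in
    blanked (artifact-interpolated) intervals are excluded from the mean.
    """
    t_start = stim_onset - cfg.baseline_window
    if t_start < rec.t0 - 1e-9:
        raise ValidationError("baseline window extends before recording start")
    i0 = rec.index_at(t_start)
    i1 = rec.index_at(stim_onset)
    keep = np.ones(i1 - i0, dtype=bool)
    for a, b in rec.blank_intervals:
        j0 = max(rec.index_at(a) - i0, 0)
        j1 = min(int(np.floor((b - rec.t0) * rec.sample_rate + 1e-9)) + 1 - i0, keep.size)
        if j1 > j0:
            keep[j0:j1] = False
    seg = rec.samples[i0:i1][keep]
    if seg.size == 0:
        raise ValidationError("baseline window contains no usable samples")
    return BaselineStats(mean_abs_amplitude=float(np.mean(np.abs(seg))),
                         window=(t_start, stim_onset),
                         n_samples_used=int(seg.size))


def condition(rec: LfpRecording, cfg: ConditioningConfig = ConditioningConfig()
              ) -> LfpRecording:
    """Full chain: blank artifacts, downsample, band-pass filter."""
    return band_filter(downsample(blank_artifacts(rec, cfg), cfg.target_rate), cfg)
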