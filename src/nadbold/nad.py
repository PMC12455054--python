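"""Detection and scoring of stimulus-evoked neuronal afterdischarges (nAD).

A short 20 Hz stimulation train in the perforant pathway triggers heavy
self-sustained spiking in the dentate gyrus. On the conditioned trace
(1000 Hz, 0.5-100 Hz band-passed) the event is scored against the animal's
own ongoing activity: the nAD ends at the first time the rectified-signal
envelope stays below ``threshold_factor`` (default 5) times the mean baseline
amplitude for longer than the persistence window (default 1 s). Intensity is
the area under the rectified curve, binned per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ephys import BaselineStats
from .io import LfpRecording, ValidationError

__all__ = [
    "NadDetectorConfig",
    "NadEvent",
    "GroupSummary",
    "envelope",
    "detect_nad_end",
    "nad_intensity",
    "summarize_group",
]


@dataclass(frozen=True)
class NadDetectorConfig:
    threshold_factor: float = 5.0
    persistence: float = 1.0
    envelope_window: float = 0.1
    max_search: float = 120.0

    def __post_init__(self):
        if min(self.threshold_factor, self.persistence, self.envelope_window) <= 0:
            raise ValidationError("detector parameters must be positive")


@dataclass
class NadEvent:
    """One detected afterdischarge.

    ``duration = nad_end - stim_end``; when no end is found within
    ``max_search`` seconds the event is censored and the duration is reported
    as the search limit. ``auc_per_second[k]`` is the integral of |x| over the
    1-s bin starting ``k`` seconds after the stimulation end (final partial
    bin pro-rata), so ``total_auc`` equals the integral over the whole event.
    """

    stim_end: float
    nad_end: float
    censored: bool = False
    auc_per_second: list = field(default_factory=list)
    total_auc: float = 0.0

    @property
    def duration(self) -> float:
        return self.nad_end - self.stim_end


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    values: list

    def __post_init__(self):
        if self.n != len(self.values):
            raise ValidationError("n must equal len(values)")


def envelope(x: np.ndarray, sample_rate: float, window: float) -> np.ndarray:
    """Centered moving mean of |x| over ``window`` seconds.

    The window length is rounded to an odd number of samples so the estimate
    is symmetric; edges use a shrinking window (normalized by the number of
    samples actually covered).
    """
    w = int(round(window * sample_rate))
    w = max(w + (1 - w % 2), 1)  # odd, >= 1
    kernel = np.ones(w)
    num = np.convolve(np.abs(x), kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_nad_end(trace: LfpRecording, stim_end: float, baseline: BaselineStats,
                   cfg: NadDetectorConfig = NadDetectorConfig()) -> NadEvent:
    """Find the end of the afterdischarge that follows a stimulation train.

    The end is the earliest time ``t >= stim_end`` at which the envelope is
    below ``threshold_factor * baseline`` for every sample of the persistence
    window ``[t, t + persistence)``. Returns a censored event with
    ``duration = max_search`` when no such time exists within the search
    range (the persistence window must fit inside the recording).
    """
    if baseline.mean_abs_amplitude <= 0:
        raise ValidationError("baseline amplitude is zero; threshold undefined")
    thr = cfg.threshold_factor * baseline.mean_abs_amplitude
    env = envelope(trace.samples, trace.sample_rate, cfg.envelope_window)
    below = env < thr

    i_start = max(trace.index_at(stim_end), 0)
    i_stop = min(trace.index_at(stim_end + cfg.max_search), trace.samples.size)
    n_persist = int(round(cfg.persistence * trace.sample_rate))

    # run-length window: candidate i qualifies iff below[i:i+n_persist].all()
    csum = np.concatenate(([0], np.cumsum(below)))
    last = below.size - n_persist
    hit = -1
    if last >= i_start:
        counts = csum[i_start + n_persist: min(i_stop, last + 1) + n_persist] \
            - csum[i_start: min(i_stop, last + 1)]
        ok = np.nonzero(counts == n_persist)[0]
        if ok.size:
            hit = i_start + int(ok[0])
    if hit < 0:
        return NadEvent(stim_end=stim_end, nad_end=stim_end + cfg.max_search,
                        censored=True)
    nad_end = trace.t0 + hit / trace.sample_rate
    return NadEvent(stim_end=stim_end, nad_end=max(nad_end, stim_end), censored=False)


def nad_intensity(trace: LfpRecording, event: NadEvent) -> NadEvent:
    """Fill the per-second AUC bins of a detected event.

    Bin ``k`` is the trapezoidal integral of |x(t)| over
    ``[stim_end + k, stim_end + k + 1)``; the final partial bin integrates
    only up to ``nad_end``.
    """
    if event.duration < 0:
        raise ValidationError("event duration must be >= 0")
    fs = trace.sample_rate
    rect = np.abs(trace.samples)
    aucs = []
    n_bins = int(np.ceil(event.duration - 1e-12))
    for k in range(n_bins):
        a = event.stim_end + k
        b = min(a + 1.0, event.nad_end)
        i0, i1 = trace.index_at(a), trace.index_at(b)
        i1 = min(max(i1 + 1, i0 + 2), rect.size)  # include the right-edge sample
        aucs.append(float(np.trapezoid(rect[i0:i1], dx=1.0 / fs)))
    event.auc_per_second = aucs
    event.total_auc = float(sum(aucs))
    return event


def summarize_group(values) -> GroupSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of per-animal values."""
    values = [float(v) for v in values]
    if len(values) < 2:
        raise ValidationError("need at least two values to summarize")
    arr = np.asarray(values)
    return GroupSummary(n=len(values), mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)), values=values)
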