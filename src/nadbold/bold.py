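"""Group analysis of BOLD VOI time series.

Per-animal series are normalized to a grand mean of 100%, averaged into group
time courses (mean +/- SD per volume), compared point-by-point with
Bonferroni-corrected t-tests, and scored for recovery of the post-stimulus
baseline decline: recovery is reached when the group mean stays at or above
98% of the pre-stimulation level (the mean over volumes 900-959, minutes
30-32 at TR = 2 s) for a sustained period. Drug and stimulus effects are
separated by subtracting the matching no-stimulation control time course.

No detrending or baseline correction is applied anywhere: the slow drifts
are part of the signal under study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import BoldSeries, ValidationError

__all__ = [
    "NormalizedSeries",
    "GroupTimecourse",
    "RecoveryConfig",
    "RecoveryResult",
    "normalize",
    "group_timecourse",
    "pointwise_difference_test",
    "recovery_time",
    "subtract_condition",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizedSeries:
    """A BOLD series rescaled so its own grand mean is exactly 100%."""

    values: np.ndarray
    tr: float
    stim_volume: int | None = None
    meta: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GroupTimecourse:
    """Per-volume mean and sample SD over the animals of one condition."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    tr: float
    condition: str = ""
    stim_volume: int | None = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValidationError("mean and sd lengths differ")


@dataclass(frozen=True)
class RecoveryConfig:
    """Recovery criterion: sustained return to 98% of the pre-stimulation level.

    ``baseline_volumes`` is an inclusive index range (default 900-959);
    ``persistence_volumes`` is the dwell requirement (default 60 volumes =
    2 min) preventing single-volume noise crossings from counting as
    recovery.
    """

    baseline_volumes: tuple = (900, 959)
    threshold_fraction: float = 0.98
    persistence_volumes: int = 60
    alpha: float = 0.01

    def __post_init__(self):
        if not (0 < self.threshold_fraction <= 1):
            raise ValidationError("threshold_fraction must be in (0, 1]")


@dataclass
class RecoveryResult:
    recovered: bool
    recovery_minutes: float | None
    baseline_value: float
    censor_time: float          # minutes of post-stimulus observation

    def __post_init__(self):
        if self.recovered and (self.recovery_minutes is None or self.recovery_minutes < 0):
            raise ValidationError("recovered events need recovery_minutes >= 0")


def normalize(series: BoldSeries) -> NormalizedSeries:
    """Rescale to percent of the series' own grand mean (mean becomes 100)."""
    m = float(series.values.mean())
    if m <= 0:
        raise ValidationError("grand mean must be positive")
    return NormalizedSeries(values=100.0 * series.values / m, tr=series.tr,
                            stim_volume=series.stim_volume, meta=dict(series.meta))


def group_timecourse(series_list, condition: str = "") -> GroupTimecourse:
    """Per-volume arithmetic mean and sample SD over animals."""
    if len(series_list) < 2:
        raise ValidationError("need at least two series")
    lengths = {s.values.size for s in series_list}
    if len(lengths) != 1:
        raise ValidationError("series lengths differ")
    trs = {s.tr for s in series_list}
    if len(trs) != 1:
        raise ValidationError("series TRs differ")
    mat = np.vstack([s.values for s in series_list])
    stim = series_list[0].stim_volume
    return GroupTimecourse(mean=mat.mean(axis=0), sd=mat.std(axis=0, ddof=1),
                           n=mat.shape[0], tr=series_list[0].tr,
                           condition=condition, stim_volume=stim)


def pointwise_difference_test(group_a: np.ndarray, group_b: np.ndarray,
                              alpha: float = 0.01, m: int | None = None,
                              paired: bool = False):
    """Per-volume t-test between two groups with Bonferroni correction.

    ``group_a``/``group_b`` are (animals x volumes) matrices. The default is
    the two-sample equal-variance (pooled) test; ``paired=True`` switches to
    a paired test on per-animal differences. A volume is significant iff
    ``p < alpha / m`` with ``m`` defaulting to the number of volumes tested.
    Volumes with zero pooled variance get ``p = 1`` by convention (logged).

    Returns ``(mask, p_values)``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValidationError("groups cover different numbers of volumes")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need >= 2 animals per group")
    n_vol = a.shape[1]
    m = n_vol if m is None else int(m)
    if m < n_vol:
        raise ValidationError("Bonferroni m smaller than number of tests")

    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValidationError("paired test needs equal group sizes")
        d = a - b
        n = d.shape[0]
        sd = d.std(axis=0, ddof=1)
        se = sd / np.sqrt(n)
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, d.mean(axis=0) / np.where(se > 0, se, 1.0), 0.0)
        degenerate = se == 0
    else:
        na, nb = a.shape[0], b.shape[0]
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0))
                         / np.where(se > 0, se, 1.0), 0.0)
        degenerate = se == 0

    p = 2.0 * sps.t.sf(np.abs(t), df)
    if degenerate.any():
        log.info("pointwise test: %d volumes with zero variance set to p=1",
                 int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
    mask = p < alpha / m
    return mask, p


def recovery_time(group: GroupTimecourse, cfg: RecoveryConfig = RecoveryConfig(),
                  stim_volume: int | None = None) -> RecoveryResult:
    """First sustained return of the group mean to the recovery threshold.

    The baseline is the mean of ``group.mean`` over ``cfg.baseline_volumes``
    (inclusive). Recovery is the first volume ``v >= stim_volume`` at which
    ``group.mean[u] >= threshold_fraction * baseline`` for all ``u`` in
    ``[v, v + persistence_volumes)``; the result is censored if no such run
    exists (a run truncated by the series end does not count).
    """
    if stim_volume is None:
        stim_volume = group.stim_volume
    if stim_volume is None:
        raise ValidationError("stim_volume required")
    b0, b1 = cfg.baseline_volumes
    if not (0 <= b0 <= b1 < stim_volume):
        raise ValidationError("baseline range must precede stim_volume")
    mean = group.mean
    baseline = float(mean[b0:b1 + 1].mean())
    thr = cfg.threshold_fraction * baseline
    ok = mean >= thr
    n_vol = mean.size
    censor_minutes = (n_vol - stim_volume) * group.tr / 60.0

    P = int(cfg.persistence_volumes)
    csum = np.concatenate(([0], np.cumsum(ok)))
    first = stim_volume
    last = n_vol - P
    if last >= first:
        counts = csum[first + P: last + 1 + P] - csum[first: last + 1]
        hits = np.nonzero(counts == P)[0]
        if hits.size:
            v = first + int(hits[0])
            minutes = (v - stim_volume) * group.tr / 60.0
            return RecoveryResult(recovered=True, recovery_minutes=minutes,
                                  baseline_value=baseline,
                                  censor_time=censor_minutes)
    return RecoveryResult(recovered=False, recovery_minutes=None,
                          baseline_value=baseline, censor_time=censor_minutes)


def subtract_condition(target: GroupTimecourse, control: GroupTimecourse
                       ) -> GroupTimecourse:
    """Remove the drug-intrinsic drift from a stimulated time course.

    ``mean_out = target.mean - control.mean + 100`` (re-anchored to the
    percent scale); SDs combine in quadrature (independent groups).
    """
    if target.mean.size != control.mean.size:
        raise ValidationError("time courses cover different numbers of volumes")
    if abs(target.tr - control.tr) > 1e-12:
        raise ValidationError("time courses have different TRs")
    return GroupTimecourse(
        mean=target.mean - control.mean + 100.0,
        sd=np.sqrt(target.sd ** 2 + control.sd ** 2),
        n=target.n, tr=target.tr,
        condition=f"{target.condition} - {control.condition}",
        stim_volume=target.stim_volume,
    )
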