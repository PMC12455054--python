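"""Inferential toolkit: pooled and paired t-tests, TOST equivalence, Bonferroni
adjustment, and the design-stage sample-size rule n = 16/Delta^2.

Every test accepts either raw per-animal values or printed summary statistics
(mean, SD, n), so group comparisons reported only as ``mean +/- SD`` remain
recomputable. Equivalence follows the two-one-sided-tests (TOST) procedure in
its 90% confidence-interval form: at alpha = 0.05, equivalence within margins
``(low, high)`` is declared exactly when the 90% CI of the group difference
lies strictly inside the margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "SummaryStats",
    "TostSpec",
    "TostResult",
    "SampleSizeSpec",
    "ttest_two_sample",
    "ttest_paired",
    "tost_equivalence",
    "bonferroni",
    "sample_size",
]


@dataclass(frozen=True)
class SummaryStats:
    """Printed group summary: mean, sample SD and group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValidationError("need >= 2 values")
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


@dataclass(frozen=True)
class TostSpec:
    margin_low: float
    margin_high: float
    alpha: float = 0.05

    def __post_init__(self):
        if not self.margin_low < self.margin_high:
            raise ValidationError("margin_low must be < margin_high")


@dataclass(frozen=True)
class TostResult:
    diff: float
    ci90: tuple
    equivalent: bool
    spec: TostSpec


@dataclass(frozen=True)
class SampleSizeSpec:
    delta_signal: float     # expected signal change (percent BOLD)
    sigma: float            # baseline variation (percent)
    Delta: float            # delta_signal / sigma
    n: float                # 16 / Delta^2 (real-valued)
    n_ceil: int


def _as_summary(x) -> SummaryStats:
    return x if isinstance(x, SummaryStats) else SummaryStats.from_values(x)


def _pooled_se(a: SummaryStats, b: SummaryStats):
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    if sp2 <= 0:
        raise ValidationError("zero pooled variance")
    return math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n)), df


def _welch_se(a: SummaryStats, b: SummaryStats):
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb <= 0:
        raise ValidationError("zero variance")
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return math.sqrt(va + vb), df


def ttest_two_sample(a, b, equal_var: bool = True):
    """Two-sample t-test from raw values or summaries.

    Default is the pooled equal-variance statistic with
    ``df = n_a + n_b - 2``; ``equal_var=False`` switches to Welch.
    Returns ``(t, df, p)`` with a two-tailed p.
    """
    a, b = _as_summary(a), _as_summary(b)
    se, df = _pooled_se(a, b) if equal_var else _welch_se(a, b)
    t = (a.mean - b.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def ttest_paired(x, y):
    """Paired t-test on matched samples; returns ``(t, df, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("paired test needs equal-length samples of size >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def tost_equivalence(a, b, spec: TostSpec) -> TostResult:
    """Equivalence of two groups by the 90% CI-inclusion form of TOST.

    ``diff = mean_a - mean_b``; the CI is ``diff +/- t_{1-alpha, df} * SE``
    with the pooled-variance SE. Equivalence holds iff the CI lies strictly
    inside ``(margin_low, margin_high)``.
    """
    a, b = _as_summary(a), _as_summary(b)
    se, df = _pooled_se(a, b)
    diff = a.mean - b.mean
    tcrit = sps.t.ppf(1.0 - spec.alpha, df)
    lo, hi = diff - tcrit * se, diff + tcrit * se
    equivalent = spec.margin_low < lo and hi < spec.margin_high
    return TostResult(diff=float(diff), ci90=(float(lo), float(hi)),
                      equivalent=bool(equivalent), spec=spec)


def bonferroni(p_values, alpha: float = 0.01, m: int | None = None) -> np.ndarray:
    """Boolean mask of tests significant under Bonferroni: ``p < alpha / m``."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValidationError("m must be >= number of p-values considered")
    return p < alpha / m


def sample_size(delta_signal: float, sigma: float) -> SampleSizeSpec:
    """Animals per group needed to resolve an effect of ``delta_signal``
    against baseline variation ``sigma``: n = 16 / (delta/sigma)^2."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    Delta = delta_signal / sigma
    n = 16.0 / Delta ** 2
    return SampleSizeSpec(delta_signal=delta_signal, sigma=sigma,
                          Delta=Delta, n=n, n_ceil=int(math.ceil(n)))
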