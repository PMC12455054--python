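"""Seeded generators for LFP sessions and BOLD VOI series with known truth.

The generators emulate the combined electrophysiology/fMRI experiment: a
122-minute session (3660 volumes at TR = 2 s) with an 8-s train of 160
bipolar pulses at 20 Hz delivered 32 minutes in (volume 960), recorded in the
dentate gyrus at 5000 Hz, under isoflurane or medetomidine with or without
acetaminophen.

Ground truth is explicit: the LFP truth fixes the afterdischarge duration
(defined as the time after the train end at which the rectified-signal
envelope crosses five times the ongoing baseline amplitude) and the BOLD
truth fixes drift regime, post-stimulus decline depth and the recovery time
of the stimulus-locked component. Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .io import BoldSeries, LfpRecording, ValidationError

__all__ = [
    "SessionDesign",
    "LfpTruth",
    "BoldTruth",
    "generate_lfp",
    "generate_bold",
    "generate_cohort",
    "save_cohort",
    "CONDITIONS_8_GROUP",
    "NAD_DURATION_REGIMES",
    "RECOVERY_REGIMES",
]


@dataclass(frozen=True)
class SessionDesign:
    """Experimental condition and acquisition geometry of one session.

    The LFP trace covers a window around the stimulation train
    (``lfp_pre`` seconds before train onset to ``lfp_post`` seconds after
    train end) rather than the full two hours, which is what the
    afterdischarge analysis consumes.
    """

    anesthetic: str = "isoflurane"           # or "medetomidine"
    acetaminophen: bool = False
    stimulated: bool = True
    tr: float = 2.0
    n_volumes: int = 3660
    stim_volume: int = 960
    lfp_rate: float = 5000.0
    n_pulses: int = 160
    pulse_rate: float = 20.0
    lfp_pre: float = 70.0
    lfp_post: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if self.anesthetic not in ("isoflurane", "medetomidine"):
            raise ValidationError("anesthetic must be isoflurane or medetomidine")

    @property
    def stim_onset(self) -> float:
        """Seconds from session start to the first pulse (32 min by default)."""
        return self.stim_volume * self.tr

    @property
    def train_duration(self) -> float:
        return self.n_pulses / self.pulse_rate

    @property
    def train_end(self) -> float:
        return self.stim_onset + self.train_duration

    @property
    def condition(self) -> str:
        tag = "med" if self.anesthetic == "medetomidine" else "iso"
        if self.acetaminophen:
            tag += "+acet"
        if not self.stimulated:
            tag += "/nostim"
        return tag


@dataclass(frozen=True)
class LfpTruth:
    """Generative parameters of one LFP session.

    ``nad_duration`` is the designed threshold-crossing time: the burst
    envelope holds at ``nad_amplitude_factor`` times the baseline amplitude,
    then decays linearly to baseline over the final stretch so that it passes
    the 5x detection threshold exactly ``nad_duration`` seconds after the
    train ends.
    """

    nad_duration: float = 13.0
    nad_amplitude_factor: float = 8.0
    baseline_amp: float = 0.05           # mV mean |amplitude| of ongoing activity
    stim_artifact_mv: float = 5.0
    gradient_artifact_mv: float = 2.0
    threshold_factor: float = 5.0        # detection threshold the truth refers to
    spike_rate: float = 40.0             # Hz, rhythmic epileptiform discharge rate
    spike_kernel_ms: float = 25.0
    noise_share: float = 0.15            # fraction of burst amplitude from noise

    def __post_init__(self):
        if self.nad_duration < 0:
            raise ValidationError("nad_duration must be >= 0")
        if self.nad_amplitude_factor <= self.threshold_factor:
            raise ValidationError("amplitude factor must exceed the detection threshold")


@dataclass(frozen=True)
class BoldTruth:
    """Generative parameters of one BOLD series (percent units around 100).

    ``recovery_minutes`` is the designed recovery of the stimulus-locked
    component: the decline returns linearly so that it re-reaches
    ``100 - recovery_loss`` percent exactly that many minutes after the
    stimulus (None = censored, no recovery within the session).
    """

    drift_model: str = "none"            # none | isoflurane | isoflurane_acet |
                                         # medetomidine | medetomidine_acet
    drift_scale: float = 1.0
    transient_amp: float = 0.0           # % positive transient (medetomidine only)
    transient_duration: float = 60.0     # seconds
    decline_depth: float = 3.0           # % initial post-stimulus decline
    recovery_minutes: Optional[float] = 41.0
    recovery_loss: float = 2.0           # % shortfall at the 98% criterion
    noise_sd: float = 0.2                # % Gaussian noise per volume
    wave_rate: float = 0.0               # spontaneous BOLD waves per hour
    wave_amp: float = 1.0                # % typical wave amplitude
    wave_width: float = 45.0             # seconds

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.recovery_minutes is not None and self.recovery_minutes <= 0:
            raise ValidationError("recovery_minutes must be > 0 or None (censored)")


# Afterdischarge-duration regimes (seconds, mean/sd) per condition.
NAD_DURATION_REGIMES = {
    "iso": (13.01, 4.42),
    "iso+acet": (11.64, 1.80),
    "med": (13.25, 1.85),
    "med+acet": (13.66, 1.87),
}

# Recovery of the stimulus-locked BOLD decline (minutes, None = censored).
RECOVERY_REGIMES = {
    "iso": None,
    "iso+acet": 70.0,
    "med": 41.0,
    "med+acet": None,
}

CONDITIONS_8_GROUP = [
    ("isoflurane", False, True), ("isoflurane", True, True),
    ("medetomidine", False, True), ("medetomidine", True, True),
    ("isoflurane", False, False), ("isoflurane", True, False),
    ("medetomidine", False, False), ("medetomidine", True, False),
]


# ---------------------------------------------------------------------------
# LFP generation
# ---------------------------------------------------------------------------

def _band_noise(n: int, fs: float, rng: np.random.Generator,
                lo: float = 2.0, hi: float = 60.0) -> np.ndarray:
    """Band-limited Gaussian noise; the spectrum sits well inside the 0.5-100 Hz
    conditioning passband so its amplitude survives the analysis chain."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(n))


def _burst_profile(t_rel: np.ndarray, truth: LfpTruth) -> tuple:
    """Envelope factor A(t) of the afterdischarge and the burst length T.

    Plateau at the amplitude factor F for the first 80% of the burst, then a
    linear decay to baseline (factor 1). T is chosen so the decay passes the
    detection threshold exactly at ``nad_duration``:
    D = T * (0.8 + 0.2 * (F - thr) / (F - 1)).
    """
    F, thr = truth.nad_amplitude_factor, truth.threshold_factor
    frac = 0.8 + 0.2 * (F - thr) / (F - 1.0)
    T = truth.nad_duration / frac
    A = np.where(t_rel < 0.8 * T, F,
                 F + (1.0 - F) * (t_rel - 0.8 * T) / (0.2 * T))
    return np.clip(A, 1.0, F), T


def generate_lfp(design: SessionDesign, truth: LfpTruth = LfpTruth(),
                 rng: np.random.Generator | None = None):
    """Simulate one in-scanner LFP recording; returns ``(recording, truth)``.

    The trace is ongoing band-limited activity (mean |x| = ``baseline_amp``)
    with a gradient-artifact transient at every volume trigger, a biphasic
    stimulation artifact at each of the 160 pulses and, for stimulated
    sessions with ``nad_duration > 0``, an afterdischarge burst starting at
    the train end. The burst is a mixture of band-limited noise and
    epileptiform spikes (Poisson train convolved with a biphasic kernel),
    amplitude-modulated so its rectified envelope follows the designed
    profile.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    fs = design.lfp_rate
    t0 = design.stim_onset - design.lfp_pre
    n = int(round((design.lfp_pre + design.train_duration + design.lfp_post) * fs))
    times = t0 + np.arange(n) / fs

    bg = _band_noise(n, fs, rng)
    bg *= truth.baseline_amp / np.mean(np.abs(bg))
    x = bg.copy()

    # afterdischarge burst replacing the background after the train end
    if design.stimulated and truth.nad_duration > 0:
        rel = times - design.train_end
        prof, T = _burst_profile(rel, truth)
        sel = (rel >= 0) & (rel < T)
        nb = int(sel.sum())
        if nb:
            # quasi-rhythmic discharge: regular spike train with per-spike
            # amplitude jitter, dense enough that the 100 ms rectified
            # envelope tracks the designed profile tightly
            kw = int(round(truth.spike_kernel_ms / 1e3 * fs))
            kernel = np.sin(2 * np.pi * np.arange(kw) / kw)
            spikes = np.zeros(nb)
            for ts in np.arange(0.0, T, 1.0 / truth.spike_rate):
                i = int(ts * fs)
                j = min(i + kw, nb)
                spikes[i:j] += rng.uniform(0.9, 1.1) * kernel[:j - i]
            spikes /= np.mean(np.abs(spikes))
            g = _band_noise(nb, fs, rng)
            g /= np.mean(np.abs(g))
            mix = (1.0 - truth.noise_share) * spikes + truth.noise_share * g
            mix /= np.mean(np.abs(mix))
            x[sel] = prof[sel] * truth.baseline_amp * mix

    # scanner volume triggers and gradient artifacts (every TR)
    first_vol = int(np.ceil((t0 - 1e-9) / design.tr))
    last_vol = min(int((times[-1]) / design.tr), design.n_volumes - 1)
    vol_triggers = np.arange(first_vol, last_vol + 1) * design.tr
    gw = int(round(0.008 * fs))
    gkernel = np.sin(2 * np.pi * 600.0 * np.arange(gw) / fs) * np.hanning(gw)
    for tv in vol_triggers:
        i = int(round((tv - t0) * fs))
        j = min(i + gw, n)
        if 0 <= i < n:
            x[i:j] += truth.gradient_artifact_mv * gkernel[:j - i]

    # stimulation pulses and their biphasic artifacts
    if design.stimulated:
        pulses = design.stim_onset + np.arange(design.n_pulses) / design.pulse_rate
        pw = int(round(0.001 * fs))
        pkernel = np.sin(2 * np.pi * np.arange(pw) / pw)
        for tp in pulses:
            i = int(round((tp - t0) * fs))
            j = min(i + pw, n)
            if 0 <= i < n:
                x[i:j] += truth.stim_artifact_mv * pkernel[:j - i]
    else:
        pulses = np.empty(0)

    rec = LfpRecording(samples=x, sample_rate=fs, t0=t0,
                       volume_triggers=vol_triggers, stim_pulses=pulses,
                       meta={"condition": design.condition, "seed": design.seed})
    return rec, truth


# ---------------------------------------------------------------------------
# BOLD generation
# ---------------------------------------------------------------------------

def _drift_percent(t_min: np.ndarray, model: str) -> np.ndarray:
    """Slow drug-intrinsic drift of the baseline BOLD signal, in percent.

    Shapes are the simplest forms consistent with the observed group time
    courses: isoflurane is a saturating vasodilation-driven rise peaking near
    +1.6% within the first hour with a shallow decay to +1.4% by two hours
    (acetaminophen delays the rise by ~60 min); medetomidine is flat for
    30 min then declines linearly to -4.9% at two hours (acetaminophen makes
    the decline start immediately, -4% by 60 min).
    """
    t = np.asarray(t_min, dtype=float)
    if model == "none":
        return np.zeros_like(t)
    if model == "isoflurane":
        # slow-onset sigmoid: near-baseline for the first ~15 min, so the
        # contrast with medetomidine only becomes resolvable around 30 min
        rise = 1.62 * (1.0 - np.exp(-((t / 25.0) ** 2)))
        peak = 1.62 * (1.0 - np.exp(-((60.0 / 25.0) ** 2)))
        late = peak + (1.39 - peak) * (t - 60.0) / 60.0
        return np.where(t <= 60.0, rise, late)
    if model == "isoflurane_acet":
        early = 0.14 * (1.0 - np.exp(-t / 10.0))
        plateau = 0.14 * (1.0 - np.exp(-60.0 / 10.0))
        late = plateau + (1.68 - plateau) * (t - 60.0) / 60.0
        return np.where(t <= 60.0, early, late)
    if model == "medetomidine":
        return np.where(t <= 30.0, 0.0, -4.93 * (t - 30.0) / 90.0)
    if model == "medetomidine_acet":
        return np.maximum(-4.01 * t / 60.0, -5.0)
    raise ValidationError(f"unknown drift model {model!r}")


def _stim_response(t_min_after: np.ndarray, truth: BoldTruth) -> np.ndarray:
    """Stimulus-locked BOLD component (percent), 0 before the stimulus.

    An optional positive transient (half-sine above baseline) right after the
    stimulus, then a step decline of ``decline_depth`` with a linear return
    that crosses ``-recovery_loss`` exactly at ``recovery_minutes`` (censored
    declines use a return too slow to cross within the session). The return
    ramp is anchored at the stimulus time, so the designed recovery time is
    unaffected by the transient.
    """
    t = np.asarray(t_min_after, dtype=float)
    out = np.zeros_like(t)
    dur = truth.transient_duration / 60.0 if truth.transient_amp > 0 else 0.0
    if truth.decline_depth > 0:
        r = truth.recovery_minutes if truth.recovery_minutes is not None else 360.0
        ramp = -truth.decline_depth + (truth.decline_depth - truth.recovery_loss) * (t / r)
        sel = t >= dur
        out[sel] = np.minimum(ramp[sel], 0.0)
    if truth.transient_amp > 0:
        tr_sel = (t >= 0) & (t < dur)
        out[tr_sel] = truth.transient_amp * np.sin(np.pi * t[tr_sel] / dur)
    return out


def generate_bold(design: SessionDesign, truth: BoldTruth = BoldTruth(),
                  rng: np.random.Generator | None = None):
    """Simulate one VOI series; returns ``(BoldSeries, truth)``.

    values = 100 + drift + stimulus response + spontaneous waves + noise,
    sampled at the volume start times (percent units; the grand mean is 100
    up to drift and noise, so :func:`nadbold.bold.normalize` is a no-op to
    within those terms).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    k = np.arange(design.n_volumes)
    t_min = k * design.tr / 60.0
    values = 100.0 + truth.drift_scale * _drift_percent(t_min, truth.drift_model)

    if design.stimulated:
        values = values + _stim_response(t_min - design.stim_onset / 60.0, truth)

    if truth.wave_rate > 0:
        session_hours = design.n_volumes * design.tr / 3600.0
        n_waves = rng.poisson(truth.wave_rate * session_hours)
        for _ in range(n_waves):
            c = rng.uniform(0, design.n_volumes * design.tr)
            amp = rng.uniform(0.5, 1.5) * truth.wave_amp * rng.choice([-1.0, 1.0])
            sigma = truth.wave_width / 4.0
            values = values + amp * np.exp(-0.5 * ((k * design.tr - c) / sigma) ** 2)

    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, design.n_volumes)

    series = BoldSeries(values=values, tr=design.tr,
                        stim_volume=design.stim_volume if design.stimulated else None,
                        meta={"condition": design.condition, "seed": design.seed})
    return series, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _default_bold_truth(design: SessionDesign, drift_scale: float = 1.0) -> BoldTruth:
    model = design.anesthetic + ("_acet" if design.acetaminophen else "")
    med = design.anesthetic == "medetomidine"
    return BoldTruth(
        drift_model=model,
        drift_scale=drift_scale,
        transient_amp=1.5 if (med and design.stimulated) else 0.0,
        decline_depth=3.0 if design.stimulated else 0.0,
        recovery_minutes=RECOVERY_REGIMES.get(
            design.condition) if design.stimulated else None,
        wave_rate=3.0 if med else 0.0,
    )


def generate_cohort(n: int = 5, seed: int = 0, conditions=CONDITIONS_8_GROUP,
                    with_lfp: bool = True, drift_scale_sd: float = 0.1,
                    min_nad_duration: float = 2.0):
    """Generate ``n`` animals for each condition; returns ``(animals, truth_table)``.

    ``animals`` is a list of dicts with keys ``design``, ``bold``,
    ``bold_truth`` and (for stimulated sessions when ``with_lfp``) ``lfp``,
    ``lfp_truth``. Afterdischarge durations are drawn per condition from the
    regime means/SDs, truncated below ``min_nad_duration``. One global seed
    expands to independent per-animal substreams, so cohorts are reproducible
    element-wise.
    """
    root = np.random.SeedSequence(seed)
    animals = []
    rows = []
    for ci, (anes, acet, stim) in enumerate(conditions):
        for a in range(n):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            design = SessionDesign(anesthetic=anes, acetaminophen=acet,
                                   stimulated=stim, seed=sub_seed)
            scale = max(float(rng.normal(1.0, drift_scale_sd)), 0.0)
            btruth = _default_bold_truth(design, drift_scale=scale)
            bold, _ = generate_bold(design, btruth, rng)
            entry = {"design": design, "bold": bold, "bold_truth": btruth,
                     "animal": a, "condition": design.condition}
            ltruth = None
            if stim and with_lfp:
                mu, sd = NAD_DURATION_REGIMES[design.condition]
                dur = float(rng.normal(mu, sd))
                while dur <= min_nad_duration:
                    dur = float(rng.normal(mu, sd))
                ltruth = LfpTruth(nad_duration=dur)
                lfp, _ = generate_lfp(design, ltruth, rng)
                entry["lfp"] = lfp
                entry["lfp_truth"] = ltruth
            rows.append({
                "condition": design.condition, "animal": a, "seed": sub_seed,
                "nad_duration_s": ltruth.nad_duration if ltruth else np.nan,
                "drift_model": btruth.drift_model,
                "drift_scale": btruth.drift_scale,
                "decline_depth_pct": btruth.decline_depth,
                "recovery_minutes": (np.nan if btruth.recovery_minutes is None
                                     else btruth.recovery_minutes),
                "censored": btruth.recovery_minutes is None and stim,
            })
            animals.append(entry)
    return animals, pd.DataFrame(rows)


def save_cohort(animals, truth_table: pd.DataFrame, outdir) -> None:
    """Write a cohort in the native on-disk formats plus a truth CSV."""
    from pathlib import Path

    from .io import write_bold_series, write_lfp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for entry in animals:
        tag = f"{entry['condition'].replace('/', '_').replace('+', '_')}_a{entry['animal']}"
        write_bold_series(entry["bold"], outdir / f"bold_{tag}.csv")
        if "lfp" in entry:
            write_lfp(entry["lfp"], outdir / f"lfp_{tag}.h5", dialect="hdf5")
    truth_table.to_csv(outdir / "truth.csv", index=False, float_format="%.10g")
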