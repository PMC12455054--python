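# Methods

This note records the models, parameter choices and numerical decisions
behind `nadbold`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and what
the synthetic benchmarks do and do not establish.

## 1. LFP conditioning

Raw in-scanner recordings (5000 Hz) carry biphasic stimulation artifacts at
each of the 160 pulses and gradient artifacts at every volume trigger
(one per TR = 2 s). The conditioning chain is **blank → decimate → filter**:

* **Blanking** replaces samples within ±5 ms of each stimulation pulse and
  ±10 ms of each volume trigger by linear interpolation between the window
  edges. Overlapping windows are merged first, so no stretch is interpolated
  twice, and blanking is idempotent at a fixed sampling rate. Blanked
  intervals are recorded on the trace and excluded from amplitude statistics.
  Blanking precedes filtering because the multi-mV transients would otherwise
  ring through the 100 Hz low-pass and contaminate the envelope for tens of
  milliseconds around every artifact.
* **Decimation** 5000 → 1000 Hz uses a zero-phase anti-alias FIR
  (`scipy.signal.decimate`); the rate ratio must be an integer.
* **Band-pass** 0.5–100 Hz is a 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`), i.e. zero phase, so event timings
  (afterdischarge end, population-spike latency) are not biased by filter
  delay. The trace mean is subtracted before filtering; traces shorter than
  three high-pass time constants (3/(2π·0.5 Hz) ≈ 0.95 s) are refused, and a
  processing flag prevents accidental double filtering.
* **Baseline amplitude** is the mean of |x| over the 60 s immediately before
  stimulation onset (window length configurable; the source protocol marks a
  pre-stimulation window without stating its length). The mean absolute
  value — not RMS — is used because the detection rule is phrased in terms of
  amplitudes, not power.

## 2. Afterdischarge detection and intensity

The detector operates on the conditioned trace. The envelope is a centered
moving mean of |x| over 100 ms — short enough to resolve the 1-s persistence
rule, long enough to bridge the gaps between individual discharges. The nAD
end is the earliest time t ≥ train end such that the envelope stays below
`threshold_factor` (default 5) times the baseline amplitude for every sample
of the persistence window (default 1 s). Events with no end within
`max_search` (default 120 s) are censored and reported at the search limit
rather than failing; the flag propagates into group tables.

Intensity is the trapezoidal integral of |x| per 1-second bin from the train
end to the detected end, with the final partial bin integrated pro-rata, so
the summed bins equal the integral over the whole event. The integral is
taken over the rectified signal rather than the envelope; the envelope is a
smoothed estimate of the same quantity and the rectified form keeps the AUC
exactly linear in trace amplitude.

The detector is vectorized (cumulative-sum run detection) but is specified —
and tested — to agree *exactly* with a naive sample-by-sample scan.

## 3. Population spikes

Evoked sweeps are scored in a post-pulse search window (default 2–10 ms,
skipping the stimulus artifact): the peak is the first sample attaining the
window maximum, the trough the first sample attaining the minimum after the
peak, amplitude = peak − trough (mV). The latency landmark is genuinely
ambiguous in the field's shorthand ("from stimulus onset"); the trough — the
conventional population-spike minimum — is primary here, with the peak time
reported alongside so either convention can be used downstream.

## 4. BOLD group analysis

* **Normalization** rescales each per-animal VOI series to its own grand
  mean (= 100%). Note the consequence: conditions with opposite drifts
  acquire opposite whole-trace offsets after normalization (a declining
  series is re-anchored upward), so pointwise tests between normalized
  groups can flag early volumes even when both conditions started at the
  same physiological level. This is inherent to grand-mean normalization,
  not an artifact of the implementation; the recovery criterion is immune to
  it because its threshold is relative to the same trace's own
  pre-stimulation baseline.
* **No detrending or baseline correction** is applied anywhere: the slow
  drifts are part of the phenomenon under study, and high-pass filtering
  would absorb exactly the sustained declines being quantified.
* **Pointwise tests** default to the two-sample equal-variance t-test,
  Bonferroni-corrected with m = number of volumes tested (3660 for a full
  session) at α = 0.01. A paired variant is available. Volumes with zero
  pooled variance get p = 1 by convention (logged), which makes "identical
  groups → empty mask" exact rather than NaN-dependent.
* **Recovery** is scored on the group-mean trace: the first volume v ≥ the
  stimulation volume from which mean[u] ≥ 0.98 × baseline for all u in
  [v, v + 60 volumes), with baseline = mean over volumes 900–959 (minutes
  30–32). The 2-minute dwell requirement prevents single-volume noise
  crossings from counting as recovery; a run truncated by the end of the
  series does not count, so such series are censored. Volume indices are
  0-based and volume k spans [k·TR, (k+1)·TR).
* **Condition subtraction** removes the drug-intrinsic drift:
  mean_out = target − control + 100, SDs combined in quadrature
  (independent groups). Recovery can be scored on either the raw or the
  subtracted trace; both are reported, since censoring on the raw trace can
  coexist with recovery of the stimulus-locked component.

## 5. Inference

t-tests accept either raw values or summary statistics (mean, SD, n) and the
two paths agree to machine precision when the summaries are exact — group
comparisons published only as mean ± SD therefore remain recomputable.
Equivalence uses the two-one-sided-tests procedure in its CI form: at
α = 0.05, equivalence within (−δ, +δ) holds iff the 90% CI
diff ± t₀.₉₅,df · SE(pooled) lies strictly inside the margins. The pooled
(equal-variance) SE is the default throughout; Welch is available but never
default. The sample-size rule n = 16/Δ² (Δ = δ/σ) is the classical quick
design formula for two-sided α = 0.05, power 0.8.

## 6. Synthetic data: what it emulates

The generators exist so every stage is testable with known truth; their
defaults encode the study conditions (TR 2 s, 3660 volumes, stimulation at
volume 960, 160 pulses at 20 Hz, 5000 Hz LFP, baseline BOLD noise
σ = 0.2%, afterdischarge durations ~13 ± 2–4 s per condition).

**LFP.** Ongoing activity is band-limited Gaussian noise (2–60 Hz, mean |x|
= 0.05 mV) — inside the conditioning passband, so its amplitude survives the
chain essentially unchanged. Gradient artifacts are 8-ms 600 Hz bursts
(2 mV) at every trigger; stimulation artifacts are 1-ms biphasic transients
(5 mV) at every pulse. The afterdischarge is a quasi-rhythmic discharge
train (regular 40 Hz, 25-ms biphasic kernel, per-spike amplitude jitter)
mixed with a 15% band-limited-noise share, amplitude-modulated by a profile
that holds at 8× baseline for 80% of the burst and then decays linearly to
baseline — with the burst length chosen so the profile passes the 5×
detection threshold exactly `nad_duration` seconds after the train end.
The designed truth is thus the threshold-crossing time itself. A sparse
Poisson spike train was rejected for this role: with a 100-ms envelope
window its rectified envelope fluctuates by tens of percent, which makes the
designed crossing unrecoverable; and kernels much shorter than ~10 ms would
be removed by the prescribed 100 Hz low-pass. Residual closure error of the
detector is ~0.1–0.2 s, dominated by envelope fluctuations near the
crossing interacting with the persistence rule (which keys on the last
excursion above threshold, a one-sided effect).

**BOLD.** values = 100 + drift + stimulus response + waves + noise, sampled
at volume start times. Drift shapes are the simplest forms consistent with
the observed group behavior, not physiological claims: isoflurane a
slow-onset sigmoid reaching ~+1.6% within the first hour and easing to
+1.4% by two hours (sigmoid onset, because the isoflurane–medetomidine
contrast should only become resolvable around minute 30); medetomidine flat
for 30 min then linear to −4.9% at two hours; acetaminophen delays the
isoflurane rise by ~60 min and makes the medetomidine decline start
immediately (−4% by 60 min). The stimulus response is an optional positive
transient (medetomidine only: 1.5%, 60 s — free parameters, the source
reports no quantitative shape) followed by a step decline (default 3%) whose
linear return crosses the 98%-criterion level exactly at the designed
recovery time; censored declines return too slowly to cross within the
session. Spontaneous BOLD waves (medetomidine only, ~3/h) are smooth signed
Gaussian bumps. One global seed expands to per-animal substreams
(`SeedSequence.spawn`), so cohorts are reproducible element-wise.

**What passing tests show — and don't.** Closure tests demonstrate that the
estimators recover the quantities they are defined on, under the stated
noise model, at the stated sizes. They do not establish performance on real
recordings, where afterdischarge envelopes are not profile-shaped, gradient
artifacts are not band-limited tones, BOLD noise is autocorrelated and
animal-to-animal variability exceeds the 10% drift-scale jitter used here.
The generated LFP covers a ~228-s window around the stimulation train
(70 s pre-onset to 150 s post-train) — all the afterdischarge analysis
consumes — rather than the full two hours.

## 7. Numerical details and degenerate inputs

* Voxel means, filters and statistics are computed in double precision
  regardless of on-disk dtype; t quantiles come from `scipy.stats.t`.
* Readers validate invariants (declared sample rate, monotone triggers,
  events within the recording span) and raise rather than coerce.
* Zero baseline amplitude makes the detection threshold undefined → error.
  Zero pooled variance → error in the scalar t-test, p = 1 by convention in
  the pointwise (vectorized) test, where a degenerate volume must not abort
  the other 3659.
* A failing animal in the pipeline is excluded and reported
  (`excluded.csv`), mirroring how sessions without usable electrophysiology
  are handled in practice; it does not abort the run.
* Pipeline outputs are written with fixed float formatting and sorted keys;
  re-running a configuration with the same seed reproduces every table
  byte-for-byte.

## 8. Known limitations

* The gradient-artifact model is a stylized tone burst; adaptive or
  regression-based MR artifact removal is out of scope (blanking suffices
  at these artifact densities).
* Recovery is scored on the group mean (matching how recovery periods are
  annotated on group traces); the per-animal mode exists but has no
  benchmark here.
* The equivalence margins used in the pipeline's drug-effect table are
  analysis inputs, not estimates; they default to the margins used in the
  motivating experiments.
* AUC intensity is reported in mV·s of the conditioned trace; comparisons
  across hardware require consistent gain, as with any absolute LFP measure.
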