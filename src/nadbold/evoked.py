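"""Population-spike measurement from single test-pulse sweeps.

Granule-cell population spikes are scored in a post-stimulus search window
(default 2-10 ms, skipping the stimulus artifact): the amplitude is the
voltage drop from the first most positive point to the following most
negative point (mV) and the latency is measured from stimulus onset (ms).
The trough is the primary latency landmark (the conventional population-spike
minimum); the peak time is reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError

__all__ = ["SweepWindow", "PopSpike", "measure_pop_spike"]


@dataclass
class SweepWindow:
    """One evoked-response sweep around a test pulse."""

    samples: np.ndarray          # mV
    sample_rate: float           # Hz
    stim_onset: float = 0.0      # seconds, on the sweep clock
    search_window: tuple = (2.0, 10.0)   # ms after stimulus onset

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        t_min, t_max = self.search_window
        n = self.samples.size
        if not (0 <= self.stim_onset + t_min / 1e3
                and self.stim_onset + t_max / 1e3 <= n / self.sample_rate):
            raise ValidationError("search window outside sweep")


@dataclass
class PopSpike:
    """Measured population spike; ``latency`` is None for a no-spike sweep."""

    amplitude: float
    latency: float | None        # ms from stimulus onset (trough landmark)
    peak_time: float | None      # ms
    trough_time: float | None    # ms
    peak_latency: float | None = None   # ms, alternative landmark


def measure_pop_spike(sweep: SweepWindow, landmark: str = "trough") -> PopSpike:
    """Score the population spike inside the search window.

    The peak is the first sample attaining the window maximum; the trough is
    the first sample attaining the minimum *after* the peak. A window with no
    peak-then-trough structure (flat, or monotonically rising so nothing
    follows the maximum) yields a no-spike result with amplitude 0.
    """
    fs = sweep.sample_rate
    t_min, t_max = sweep.search_window
    i0 = int(np.ceil((sweep.stim_onset + t_min / 1e3) * fs - 1e-9))
    i1 = int(np.floor((sweep.stim_onset + t_max / 1e3) * fs + 1e-9)) + 1
    win = sweep.samples[i0:i1]
    if win.size < 2:
        raise ValidationError("search window too short")

    ipk = int(np.argmax(win))
    after = win[ipk + 1:]
    if after.size == 0 or np.ptp(win) == 0:
        return PopSpike(amplitude=0.0, latency=None, peak_time=None, trough_time=None)
    itr = ipk + 1 + int(np.argmin(after))
    amp = float(win[ipk] - win[itr])
    if amp <= 0:
        return PopSpike(amplitude=0.0, latency=None, peak_time=None, trough_time=None)

    to_ms = lambda i: float(((i0 + i) / fs - sweep.stim_onset) * 1e3)
    peak_ms, trough_ms = to_ms(ipk), to_ms(itr)
    latency = trough_ms if landmark == "trough" else peak_ms
    return PopSpike(amplitude=amp, latency=latency,
                    peak_time=peak_ms, trough_time=trough_ms,
                    peak_latency=peak_ms)
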