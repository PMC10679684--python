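"""Threshold-crossing spike detection from raw extracellular traces.

Traces are bandpass filtered (4-4000 Hz at 10 kHz by default) and spikes
are detected as downward crossings of -multiplier x SD of the baseline
noise, with the SD estimated robustly (median absolute deviation) so that
the spikes themselves do not inflate the noise estimate.  Only the negative
threshold is used; extracellular action potentials present as sharp
negative deflections at the electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .geometry import ElectrodeAddress, SpikeTrain

_MAD_TO_SD = 1.0 / stats.norm.ppf(0.75)  # ~1.4826


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection settings.

    ``threshold_multiplier`` scales the estimated noise SD (default 6.5);
    the band defaults to 4-4000 Hz at a 10 kHz sampling rate, and
    consecutive detections are separated by at least ``refractory_s``.
    """

    threshold_multiplier: float = 6.5
    band_low_hz: float = 4.0
    band_high_hz: float = 4000.0
    sampling_hz: float = 10_000.0
    refractory_s: float = 0.001
    robust_sd: bool = True

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        nyquist = self.sampling_hz / 2.0
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ValueError(
                f"need 0 < low < high < Nyquist ({nyquist} Hz); got "
                f"[{self.band_low_hz}, {self.band_high_hz}]"
            )
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


def bandpass(trace: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth bandpass of a raw trace."""
    sos = signal.butter(
        2,
        [params.band_low_hz, params.band_high_hz],
        btype="bandpass",
        fs=params.sampling_hz,
        output="sos",
    )
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_noise_sd(
    trace: np.ndarray,
    params: DetectionParams | None = None,
    filtered: bool = False,
) -> float:
    """Robust baseline-noise SD (uV) of a trace.

    Uses the scaled median absolute deviation by default, which is nearly
    unbiased for Gaussian noise yet insensitive to the sparse large
    deflections produced by spikes.  Set ``params.robust_sd=False`` for the
    plain sample SD.
    """
    params = params or DetectionParams()
    x = np.asarray(trace, dtype=float)
    if x.size < params.sampling_hz:
        raise ValueError("need at least 1 s of samples to estimate noise")
    if not filtered:
        x = bandpass(x, params)
    if params.robust_sd:
        return float(stats.median_abs_deviation(x) * _MAD_TO_SD)
    return float(np.std(x))


def detection_threshold(trace: np.ndarray, params: DetectionParams | None = None) -> float:
    """Voltage threshold (uV, negative) applied to the bandpassed trace."""
    params = params or DetectionParams()
    return -params.threshold_multiplier * estimate_noise_sd(trace, params)


def detect_spikes(
    trace: np.ndarray,
    params: DetectionParams | None = None,
    address: ElectrodeAddress | None = None,
) -> SpikeTrain:
    """Detect threshold-crossing spikes on a raw voltage trace.

    The trace is bandpassed, the noise SD estimated, and every downward
    crossing of ``-multiplier * SD`` yields one spike, suppressing further
    detections for the refractory window.  Timestamps are the crossing
    sample divided by the sampling rate.
    """
    params = params or DetectionParams()
    x = bandpass(trace, params)
    sd = estimate_noise_sd(x, params, filtered=True)
    duration = x.size / params.sampling_hz
    addr = address or ElectrodeAddress(1, 1, 1)
    if sd == 0.0:
        return SpikeTrain(addr, np.empty(0), duration=duration)
    thr = -params.threshold_multiplier * sd
    below = x < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.concatenate([[0], crossings])
    # enforce refractory: keep a crossing only if >= refractory after the last kept one
    refr = int(round(params.refractory_s * params.sampling_hz))
    kept = []
    last = -refr - 1
    for c in crossings:
        if c - last > refr:
            kept.append(c)
            last = c
    times = np.asarray(kept, dtype=float) / params.sampling_hz
    return SpikeTrain(addr, times, duration=duration)
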