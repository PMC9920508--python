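"""Software equivalents of the device's analog conditioning chain.

DC removal (AC coupling), Butterworth band-pass filtering for the ECG
(0.05–100 Hz) and the microphone pulse wave (default 10–40 Hz, bracketing
the 25 Hz main component), and FFT-based dominant-frequency estimation.

Filtering defaults to zero-phase (forward-backward) application: the
pipeline's output is a timing measurement, and the group delay of a causal
filter would bias every transit time.  Causal application remains available
via ``FilterSpec(zero_phase=False)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "ECG_BAND",
    "MIC_BAND",
    "remove_dc",
    "bandpass",
    "dominant_frequency",
]

#: ECG signal band of interest (Hz).
ECG_BAND = (0.05, 100.0)
#: Pulse-wave band (Hz): brackets the 25 Hz main component while rejecting
#: baseline wander below and powerline interference above.
MIC_BAND = (10.0, 40.0)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter description.

    order is the Butterworth design order of the one-way filter;
    forward-backward application doubles the effective rolloff.
    """

    low_cut: float
    high_cut: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2
        if not (0 <= self.low_cut < self.high_cut):
            raise ValueError(
                f"require 0 <= low_cut < high_cut, got ({self.low_cut}, {self.high_cut})"
            )
        if self.high_cut >= nyquist:
            raise ValueError(
                f"high_cut {self.high_cut} Hz must lie below Nyquist "
                f"({nyquist} Hz at fs={sampling_rate})"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")


def remove_dc(signal: np.ndarray, sampling_rate: float) -> np.ndarray:
    """AC coupling: subtract the signal's mean."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("cannot remove DC from an empty signal")
    return signal - signal.mean()


def bandpass(
    signal: np.ndarray, sampling_rate: float, spec: FilterSpec
) -> np.ndarray:
    """Butterworth band-pass; zero-phase (filtfilt) when spec.zero_phase."""
    spec.validate(sampling_rate)
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("cannot filter an empty signal")
    nyquist = sampling_rate / 2
    if spec.low_cut > 0:
        wn = (spec.low_cut / nyquist, spec.high_cut / nyquist)
        sos = sps.butter(spec.order, wn, btype="bandpass", output="sos")
    else:
        sos = sps.butter(
            spec.order, spec.high_cut / nyquist, btype="lowpass", output="sos"
        )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, signal)
    return sps.sosfilt(sos, signal)


def dominant_frequency(signal: np.ndarray, sampling_rate: float) -> float:
    """Frequency (Hz) of the magnitude-spectrum maximum, DC bin excluded.

    A single full-length unwindowed transform; frequency resolution is
    1/duration, so at least 2 s of signal are required for <= 0.5 Hz bins.
    """
    signal = np.asarray(signal, dtype=float)
    min_samples = int(2 * sampling_rate)
    if signal.size < min_samples:
        raise ValueError(
            f"signal too short for spectral analysis: need >= {min_samples} "
            f"samples (2 s at fs={sampling_rate}), got {signal.size}"
        )
    spectrum = np.abs(np.fft.rfft(signal))
    freqs = np.fft.rfftfreq(signal.size, d=1.0 / sampling_rate)
    peak = 1 + int(np.argmax(spectrum[1:]))  # exclude DC
    return float(freqs[peak])
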