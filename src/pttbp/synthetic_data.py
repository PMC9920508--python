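"""Synthetic dual-channel ECG + radial-artery pulse-wave generator.

Stands in for the hardware front-end (chest electrodes + wrist MEMS
microphone sampled at 1 kHz): produces two synchronized channels with
per-beat ground truth, so every downstream stage — filtering, R-peak
detection, pulse-wave feature extraction, the PTT→BP model and the
evaluation statistics — can be exercised without recorded data.

The ECG channel is a P-QRS-T template built from Gaussian bumps; only the
R deflection's sharpness and dominance are contractual, since the pipeline
uses the ECG solely as a cardiac timing fiducial.

The microphone channel is, per beat, a single oscillatory wavelet whose
carrier runs at ``mic_main_freq`` (25 Hz by default — the dominant
spectral component of the radial-artery sound).  The carrier phase is
pinned so that the wavelet's deepest negative extremum falls exactly at
``r + ptt1`` (systolic feature) and its highest subsequent positive
extremum exactly at ``r + ptt2`` (diastolic feature); between the two
features the instantaneous frequency is re-rated to the nearest
half-cycle count so the phase pins are exact for arbitrary (ptt1, ptt2).
An exponential ringdown at the carrier frequency after the second feature
anchors the waveform's spectral line at ``mic_main_freq``.

Optional additive contaminants per channel: white noise, 0.3 Hz baseline
wander, and powerline interference.  A single integer seed controls all
stochastic draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bp_model import SubjectProfile, estimate_bp, invert_bp

__all__ = [
    "ValidationError",
    "ChannelNoise",
    "ScenarioSpec",
    "SignalRecord",
    "DEFAULT_ECG_NOISE",
    "DEFAULT_MIC_NOISE",
    "generate_ecg",
    "generate_mic",
    "generate_record",
]


class ValidationError(ValueError):
    """Raised when a scenario violates one of its stated invariants."""


PerBeat = Union[float, Sequence[float]]


@dataclass(frozen=True)
class ChannelNoise:
    """Additive contaminant amplitudes for one channel (signal units).

    ``white`` is a standard deviation; ``baseline_wander`` and
    ``powerline`` are sinusoid amplitudes at ``baseline_freq`` /
    ``powerline_freq`` with random phase.
    """

    white: float = 0.0
    baseline_wander: float = 0.0
    powerline: float = 0.0
    baseline_freq: float = 0.3
    powerline_freq: float = 60.0

    def __post_init__(self) -> None:
        for name in ("white", "baseline_wander", "powerline"):
            if getattr(self, name) < 0:
                raise ValidationError(f"noise amplitude {name} must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.white == 0 and self.baseline_wander == 0 and self.powerline == 0


#: Realistic default contamination for a wearable chest-lead ECG (mV) and a
#: skin-coupled MEMS microphone channel (V): broadband noise at a few percent
#: of the signal amplitude plus respiration-band wander and mains pickup.
DEFAULT_ECG_NOISE = ChannelNoise(white=0.05, baseline_wander=0.10, powerline=0.02)
DEFAULT_MIC_NOISE = ChannelNoise(white=0.03, baseline_wander=0.05, powerline=0.02)

# ECG template: (amplitude mV, centre offset from R in s, Gaussian sigma s).
# R is ~3.7x the largest other deflection, satisfying the >=3x dominance
# contract needed for unambiguous peak detection.
_ECG_WAVES = (
    (0.15, -0.200, 0.025),   # P
    (-0.10, -0.028, 0.010),  # Q
    (1.10, 0.000, 0.009),    # R
    (-0.15, 0.028, 0.010),   # S
    (0.30, 0.280, 0.045),    # T
)

# Mic wavelet envelope parameters (relative units; the composed channel is
# rescaled so its peak magnitude equals mic_amplitude exactly).
_MIC_A1 = 1.0        # depth of the negative (systolic) feature
_MIC_A2 = 0.85       # height of the positive (diastolic) feature
_MIC_SIGMA1 = 0.022  # s, Gaussian half-width around the negative feature
_MIC_SIGMA2 = 0.016  # s, Gaussian half-width around the positive feature
# Ringdown after the positive feature: fast initial decay (separates the
# feature lobe from its successors) plus a low-amplitude slow tail whose
# many coherent carrier cycles anchor the spectral line at mic_main_freq.
_MIC_TAU_FAST = 0.12   # s, initial decay
_MIC_TAU_SLOW = 0.25   # s, coherent tail
_MIC_TAIL_W = 0.80     # fraction of a2 carried by the slow tail


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of one synthetic recording session.

    Per-beat ground truth is given either as transit times (``ptt1``,
    ``ptt2``, seconds) or as pressure targets (``sbp``, ``dbp``, mmHg);
    pressure targets are converted to transit times by inverting the BP
    model for the subject at record-generation time.  Scalars broadcast to
    every beat; sequences must have one entry per beat.
    """

    duration: float
    heart_rate: float = 60.0
    sampling_rate: float = 1000.0
    ptt1: Optional[PerBeat] = None
    ptt2: Optional[PerBeat] = None
    sbp: Optional[PerBeat] = None
    dbp: Optional[PerBeat] = None
    mic_main_freq: float = 25.0
    mic_amplitude: float = 1.1
    ecg_noise: ChannelNoise = field(default_factory=ChannelNoise)
    mic_noise: ChannelNoise = field(default_factory=ChannelNoise)
    first_beat_time: float = 0.3
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValidationError("duration must be > 0 s")
        if not (self.heart_rate > 0):
            raise ValidationError("heart_rate must be > 0 beats/min")
        if self.sampling_rate < 200:
            raise ValidationError(
                "sampling_rate must be >= 200 Hz to resolve the 25 Hz pulse "
                "component and sub-5-ms timing"
            )
        if not (0 < self.mic_main_freq < self.sampling_rate / 2):
            raise ValidationError("mic_main_freq must lie below Nyquist")
        if not (self.mic_amplitude > 0):
            raise ValidationError("mic_amplitude must be > 0 V")
        has_ptt = self.ptt1 is not None or self.ptt2 is not None
        has_bp = self.sbp is not None or self.dbp is not None
        if has_ptt and has_bp:
            raise ValidationError("specify either PTT pairs or BP pairs, not both")
        if has_ptt and (self.ptt1 is None or self.ptt2 is None):
            raise ValidationError("both ptt1 and ptt2 must be given")
        if has_bp and (self.sbp is None or self.dbp is None):
            raise ValidationError("both sbp and dbp must be given")
        if not has_ptt and not has_bp:
            # default operating point: the canonical single-beat example
            object.__setattr__(self, "ptt1", 0.222)
            object.__setattr__(self, "ptt2", 0.292)

    # -- beat schedule -----------------------------------------------------

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def r_times(self) -> np.ndarray:
        """Scheduled R-peak times, snapped to the sample grid."""
        times = np.arange(self.first_beat_time, self.duration, self.beat_period)
        return np.round(times * self.sampling_rate) / self.sampling_rate

    def _per_beat(self, value: PerBeat, name: str, n: int) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.full(n, arr[0])
        if arr.size != n:
            raise ValidationError(
                f"{name} has {arr.size} entries for {n} scheduled beats"
            )
        return arr

    def beat_ptts(
        self, subject: Optional[SubjectProfile] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-beat (ptt1, ptt2) arrays, inverting the BP model if needed.

        Raises
        ------
        ValidationError
            If a PTT invariant (0 < ptt1 < ptt2 < beat period) is violated.
        DomainError
            If a BP target lies at or below the model asymptote.
        """
        n = len(self.r_times())
        if self.ptt1 is not None:
            p1 = self._per_beat(self.ptt1, "ptt1", n)
            p2 = self._per_beat(self.ptt2, "ptt2", n)
        else:
            if subject is None:
                raise ValidationError(
                    "scenario specifies BP targets; a SubjectProfile is "
                    "required to invert the model"
                )
            sbp = self._per_beat(self.sbp, "sbp", n)
            dbp = self._per_beat(self.dbp, "dbp", n)
            p1 = np.array([invert_bp(v, subject) for v in sbp])
            p2 = np.array([invert_bp(v, subject) for v in dbp])
        if np.any(p1 <= 0) or np.any(p2 <= p1):
            raise ValidationError("invariant violated: 0 < ptt1 < ptt2 per beat")
        if np.any(p2 >= self.beat_period):
            raise ValidationError(
                "invariant violated: beat period 60/heart_rate > ptt2 per beat"
            )
        return p1, p2


@dataclass
class SignalRecord:
    """Two synchronized sampled channels with metadata and ground truth.

    ``ecg`` is in millivolts, ``mic`` in volts; both share
    ``sampling_rate``.  ``ground_truth`` (when present) is a DataFrame with
    columns ``r_time, ptt1, ptt2, sbp, dbp`` — one row per generated beat.
    """

    sampling_rate: float
    ecg: np.ndarray
    mic: np.ndarray
    start_time: float = 0.0
    subject: Optional[SubjectProfile] = None
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.mic = np.asarray(self.mic, dtype=float)
        if self.ecg.shape != self.mic.shape or self.ecg.ndim != 1:
            raise ValidationError("ecg and mic channels must be 1-D and equal length")

    @property
    def n_samples(self) -> int:
        return self.ecg.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


# ---------------------------------------------------------------------------
# channel synthesis
# ---------------------------------------------------------------------------


def _add_noise(
    signal: np.ndarray,
    noise: ChannelNoise,
    sampling_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if noise.is_zero:
        return signal
    t = np.arange(signal.size) / sampling_rate
    out = signal.copy()
    if noise.white > 0:
        out += rng.normal(0.0, noise.white, signal.size)
    if noise.baseline_wander > 0:
        out += noise.baseline_wander * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline > 0:
        out += noise.powerline * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    return out


def generate_ecg(scenario: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the ECG channel (mV).

    Returns ``(ecg, r_times)`` where ``r_times`` are the true R-peak times
    in seconds.  Each beat is a P-QRS-T sum of Gaussian bumps whose R
    deflection is the unique dominant narrow positive peak.
    """
    fs = scenario.sampling_rate
    n = scenario.n_samples
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    r_times = scenario.r_times()
    for r in r_times:
        for amp, center, sigma in _ECG_WAVES:
            lo = max(0, int((r + center - 5 * sigma) * fs))
            hi = min(n, int((r + center + 5 * sigma) * fs) + 1)
            if lo >= hi:
                continue
            dt = t[lo:hi] - (r + center)
            ecg[lo:hi] += amp * np.exp(-0.5 * (dt / sigma) ** 2)
    rng = np.random.default_rng([scenario.random_seed, 0])
    ecg = _add_noise(ecg, scenario.ecg_noise, fs, rng)
    return ecg, r_times


def _mic_wavelet(
    t: np.ndarray, ptt1: float, ptt2: float, f: float
) -> np.ndarray:
    """One beat's clean pulse-wave wavelet on times ``t`` relative to the R-peak.

    Carrier phase is pinned to an exact cosine minimum at ``ptt1`` and an
    exact maximum at ``ptt2``; between the features the phase advances
    linearly by the odd half-cycle count closest to ``f * (ptt2 - ptt1)``.
    """
    delta = ptt2 - ptt1
    m = max(1, round(f * delta + 0.5))  # phase pi -> 2*pi*m across the gap
    phase = np.empty_like(t)
    before = t <= ptt1
    between = (t > ptt1) & (t < ptt2)
    after = t >= ptt2
    phase[before] = np.pi + 2 * np.pi * f * (t[before] - ptt1)
    phase[between] = np.pi + (2 * m - 1) * np.pi * (t[between] - ptt1) / delta
    phase[after] = 2 * np.pi * m + 2 * np.pi * f * (t[after] - ptt2)

    hump1 = _MIC_A1 * np.exp(-0.5 * ((t - ptt1) / _MIC_SIGMA1) ** 2)
    hump2 = _MIC_A2 * np.exp(-0.5 * ((t - ptt2) / _MIC_SIGMA2) ** 2)
    dt2 = np.maximum(t - ptt2, 0.0)
    ringdown = _MIC_A2 * (
        (1 - _MIC_TAIL_W) * np.exp(-dt2 / _MIC_TAU_FAST)
        + _MIC_TAIL_W * np.exp(-dt2 / _MIC_TAU_SLOW)
    )
    env = np.where(t < ptt2, hump1 + np.where(between, hump2, 0.0), hump1 + ringdown)
    return env * np.cos(phase)


def generate_mic(
    r_peak_times: Sequence[float],
    scenario: ScenarioSpec,
    subject: Optional[SubjectProfile] = None,
) -> np.ndarray:
    """Synthesize the microphone pulse-wave channel (V).

    For each R-peak at time ``r`` the clean channel's most-negative
    extremum in the following beat falls at ``r + ptt1`` and its
    most-positive extremum after that at ``r + ptt2``; the composed clean
    channel's peak magnitude equals ``mic_amplitude`` exactly and its
    dominant spectral component sits at ``mic_main_freq``.
    """
    fs = scenario.sampling_rate
    n = scenario.n_samples
    mic = np.zeros(n)
    r_peak_times = np.asarray(r_peak_times, dtype=float)
    if r_peak_times.size:
        p1, p2 = scenario.beat_ptts(subject)
        if p1.size != r_peak_times.size:
            raise ValidationError(
                "per-beat PTT count does not match the number of R-peaks"
            )
        for r, ptt1, ptt2 in zip(r_peak_times, p1, p2):
            lo = max(0, int((r + ptt1 - 5 * _MIC_SIGMA1) * fs))
            hi = min(n, int((r + ptt2 + 5 * _MIC_TAU_SLOW) * fs) + 1)
            if lo >= hi:
                continue
            t = np.arange(lo, hi) / fs - r
            mic[lo:hi] += _mic_wavelet(t, ptt1, ptt2, scenario.mic_main_freq)
        peak = np.max(np.abs(mic))
        if peak > 0:
            mic *= scenario.mic_amplitude / peak
    rng = np.random.default_rng([scenario.random_seed, 1])
    return _add_noise(mic, scenario.mic_noise, fs, rng)


def generate_record(
    scenario: ScenarioSpec, subject: SubjectProfile
) -> SignalRecord:
    """Generate a complete two-channel record with per-beat ground truth.

    When the scenario specifies pressure targets, the stored ground-truth
    transit times are the exact model inversion of those targets, so
    ``estimate_bp(ptt1, ptt2)`` round-trips to the programmed pressures.
    """
    ecg, r_times = generate_ecg(scenario)
    mic = generate_mic(r_times, scenario, subject)
    p1, p2 = scenario.beat_ptts(subject)
    rows = []
    for r, ptt1, ptt2 in zip(r_times, p1, p2):
        est = estimate_bp(ptt1, ptt2, subject, beat_time=r)
        rows.append((r, ptt1, ptt2, est.sbp, est.dbp))
    ground_truth = pd.DataFrame(
        rows, columns=["r_time", "ptt1", "ptt2", "sbp", "dbp"]
    )
    return SignalRecord(
        sampling_rate=scenario.sampling_rate,
        ecg=ecg,
        mic=mic,
        subject=subject,
        ground_truth=ground_truth,
    )
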