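# Methods

## The measurement principle

Arterial pulse waves travel faster when pressure (and hence wall stiffness)
is higher, so the transit time from cardiac electrical activation to pulse
arrival at a peripheral site is inversely related to blood pressure.  This
package models a wrist-worn variant of that principle: the timing fiducial
is the ECG R-peak, and the arrival sensor is a MEMS microphone over the
radial artery whose membrane is driven by the sound of pulsatile flow.  The
microphone waveform differs from an optical (PPG) pulse: its first
*negative* extremum marks the moment of maximum ejection (systolic feature,
delay PTT1) and the following *positive* extremum marks the diastolic
feature (delay PTT2).

## Pressure model

For each beat,

    BP = (1/0.7) · ( ½·ρ·(d/PTT)² + ρ·g·h )  +  B·(133.322 Pa/mmHg)

evaluated in pascals and reported in mmHg.  Parameters:

| parameter | meaning | unit | default |
|---|---|---|---|
| `height` | subject height; path length d = 0.48·height | m | — (required) |
| `blood_density` (ρ) | blood mass density | kg/m³ | 1035 |
| `arm_offset` (h) | wrist's vertical offset below heart level | m | 0 |
| `correction_B` (B) | fixed additive correction | mmHg | 40 |

The kinetic prefactor collapses to `A = (0.48·height)²·ρ/1.4` (the ½ and
1/0.7 folded together; the code enforces `1.4 = 2×0.7` structurally).
PTT1 maps to SBP and PTT2 to DBP.  Design choices made where the model
statement leaves room:

- **Units.** The bracketed terms are dimensionally pascals when evaluated
  from SI inputs, while B and all outputs are in mmHg.  The only
  self-consistent reading — and the one that lands 222/292 ms near
  113/83 mmHg for a ~1.7 m subject — evaluates the bracket in Pa, divides
  by 133.322, then adds B.  That convention is fixed here.
- **Hydrostatic scaling.** The ρgh term sits inside the bracket and is
  therefore also divided by 0.7.  Lowering the wrist 0.3 m below heart
  level raises both pressures by ≈ 32.6 mmHg.
- **Inversion.** `invert_bp` is the closed-form inverse
  `PTT = sqrt(A / ((BP−B)·133.322 − ρgh/0.7))`, defined strictly above the
  asymptote `B + ρgh/(0.7·133.322)`; the simulator uses it to program
  records by target pressure, and estimate∘invert round-trips to 1e−9.
- **Calibration.** `calibrate_B` solves the model for B at one
  (PTT, reference) pair; no ongoing recalibration is modelled.

The worked operating point 222/292 ms → 113/83 mmHg cannot be pinned
exactly because the original subject's height and B are not published;
with height ∈ [1.65, 1.75] m and B ∈ [38, 42] mmHg the model reaches
113/83 within ±2 mmHg (e.g. 1.70 m / B=40 gives 114.9/83.3), which is what
the acceptance suite verifies.

## Synthetic data generator

The generator replaces the hardware front end (electrodes, amplifier,
analog filters, 1 kHz MCU sampling) and defines the conditions under which
the pipeline is validated.

**ECG channel (mV).**  Each beat is a P-QRS-T sum of Gaussian bumps; the R
deflection (1.1 mV, σ = 9 ms) is ≥ 3× every other deflection, making the
R-peak the unambiguous per-beat maximum.  Only R timing is contractual —
the pipeline uses the ECG solely as a fiducial.  Scheduled R times are
snapped to the sample grid.

**Microphone channel (V).**  Per beat, a single oscillatory wavelet with:

- carrier at `mic_main_freq` (default 25 Hz, the dominant component of the
  radial-artery sound) outside the two feature points;
- carrier phase *pinned* to an exact cosine minimum at `r + ptt1` and an
  exact maximum at `r + ptt2`.  Between the features the phase advances
  linearly by the odd half-cycle count closest to `f·(ptt2−ptt1)`, so
  arbitrary feature spacings are honoured exactly (at π-phase pins the
  envelope slope cannot displace the extremum by more than a fraction of a
  sample);
- a Gaussian attack/hump envelope around each feature (σ = 22 / 16 ms,
  relative amplitudes 1.0 / 0.85) and, after the second feature, a
  two-time-constant ringdown (0.12 s initial, 0.25 s coherent tail at 80 %
  weight).  The tail's many coherent carrier cycles concentrate spectral
  mass at `mic_main_freq`; the initial decay keeps the first post-feature
  lobe well below the feature itself so band-pass filtering cannot promote
  a neighbouring lobe;
- per-record rescaling so the clean peak magnitude equals `mic_amplitude`
  (default 1.1 V).  The hardware's ×3 amplification is represented only by
  this amplitude.

**Noise.**  Optional additive white noise, 0.3 Hz baseline wander and
powerline (60 Hz) sinusoids per channel, all seeded from a single integer.
The packaged default levels (`DEFAULT_ECG_NOISE`: σ = 0.05 mV white,
0.10 mV wander, 0.02 mV mains; `DEFAULT_MIC_NOISE`: 0.03 V / 0.05 V /
0.02 V) correspond to a few percent of each channel's signal amplitude —
an ordinary, well-coupled wearable recording.

**What the generator does not emulate.**  Beat-to-beat heart-rate
variability and arrhythmia; motion artefacts and sensor-contact changes;
any physiological coupling between heart rate and transit time; electrode
or acoustic physics.  Passing tests therefore demonstrate that the
*algorithmic* chain is correct and noise-tolerant at realistic
contamination levels, not that the device would meet AAMI bounds on real
subjects.

**Spectral scope.**  A beat train is periodic, so its spectrum is a comb
at heart-rate harmonics under the wavelet's envelope: the measured
dominant frequency can equal 25.00 Hz only when 25 Hz is (near) a harmonic
of the beat rate, and only for constant per-beat transit times.  The
bin-exact spectral property is therefore stated and tested for
constant-PTT records at such rates (50, 60, 75, 100 bpm; the default is
60); per-beat varying PTTs scatter the peak within ~1 Hz.

## Signal conditioning and detection

- **Filters.**  Butterworth band-passes applied forward–backward
  (zero-phase) by default: ECG analysis band 0.05–100 Hz (QRS-emphasis
  5–15 Hz inside the R-detector), pulse-wave band 10–40 Hz around the
  25 Hz main component.  Zero-phase application is a deliberate departure
  from the causal analog chain being modelled: PTT is a timing
  measurement, and a causal filter's group delay would bias every
  transit time.  One-octave-out attenuation exceeds 20 dB at the default
  order (4).
- **R-peak detection** (unspecified by the source device): classical
  derivative–square–integrate front end with adaptive signal/noise
  thresholds, 250 ms refractory period, and refinement to the local ECG
  maximum within ±25 ms.
- **Pulse-wave features.**  Global minimum of the band-passed microphone
  signal within [0.10, 0.50] s after each R-peak, then the global maximum
  strictly after that minimum.  Global extrema (not first-crossing peaks)
  are deterministic under noise; ties break to the earliest sample.
  Extrema landing on a window boundary flag the beat `out_of_bounds`.
- **Bounds filter.**  Retained beats must satisfy
  0.08 s ≤ PTT1 < PTT2 ≤ 0.60 s.
- **Timing resolution** stays at the sample level (1 ms at 1 kHz); no
  sub-sample interpolation, matching the modelled device's MCU sampling.

## Evaluation statistics

Per-beat estimates are paired with cuff references by averaging all beats
within ±60 s of each reference timestamp (references are nominally 2 min
apart, so the window partitions the session); unmatched references are
dropped and counted.  `sd` implements the deviation formula literally —
signed differences centred on the MAE — because that is how the modelled
study defines it; it coincides with an ordinary SD only when all errors
share one sign, and `conventional_sd` is provided separately.  AAMI bounds
are applied inclusively (≤ 5 / ≤ 8 mmHg).  Reported values round half-up
to 2 decimals.

The package ships the 15-session error table of the five-day single-subject
reproducibility study it models (`FIVE_DAY_SESSIONS`).  One printed cell
(Day 2 09:00 DBP SD "0.084") is inconsistent with that table's own printed
column average; the self-consistent reading 0.84 is the default and the
literal value is kept in `FIVE_DAY_SESSIONS_AS_PRINTED`.  (The study's
abstract also swaps the SBP/DBP labels of the averaged errors relative to
the table; the table's column labels are followed here.)

## Problem sizes

Test and acceptance runs use 10–101 s records at 1 kHz for unit and
round-trip checks, a 101-beat sweep for PTT-recovery properties, and one
20-minute (1.2 M sample) default-noise session for the end-to-end AAMI
check — ample for every statistic computed while keeping the suite fast.

## Known limitations

- Single-subject model: A is assumed population-constant; only B is
  calibratable.
- The evaluation pairs a real-time estimator against sparse cuff readings;
  the pairing window is a modelling choice, not a physiological one.
- WFDB/EDF import adapters are interface stubs; the native format is
  CSV + JSON sidecar.
- No sub-sample timing; at 1 kHz this bounds PTT precision to ±0.5 ms and
  BP precision to roughly ±0.4 mmHg at the default operating point.
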