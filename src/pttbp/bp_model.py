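"""Hydrodynamic pulse-transit-time → blood-pressure model.

Blood pressure at a peripheral site is modelled as the sum of a kinetic
term and a hydrostatic term, scaled by an empirical factor and offset by a
fixed correction constant:

    BP = (1/0.7) * ( (1/2) * rho * (d / PTT)**2 + rho * g * h ) + B

with ``d = 0.48 * height`` the effective heart-to-wrist path length, ``rho``
the blood density (1035 kg/m^3 on average), ``g`` gravitational
acceleration, ``h`` the vertical offset of the wrist below heart level, and
``B`` a per-subject correction constant (about 40 mmHg).  Collecting the
kinetic prefactor gives ``BP = A / PTT**2 + (hydrostatic) + B`` with

    A = (0.48 * height)**2 * rho / 1.4

The bracketed terms are dimensionally pascals (SI inputs), so they are
converted to mmHg (divide by 133.322) before adding B, which is specified
in mmHg.  PTT1 (R-peak to the pulse wave's first negative extremum) maps to
systolic pressure, PTT2 (R-peak to the subsequent positive extremum) to
diastolic pressure; shorter transit times mean stiffer, higher-pressure
arteries, so BP is strictly decreasing in PTT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DomainError",
    "ModelConstants",
    "SubjectProfile",
    "BPEstimate",
    "coefficient_A",
    "estimate_bp",
    "invert_bp",
    "calibrate_B",
]


class DomainError(ValueError):
    """Raised when a model input lies outside the model's domain."""


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants and structural factors of the BP model.

    ``denom == 2 * scale`` by construction: the 1.4 in the kinetic
    coefficient is the 1/2 kinetic-energy factor folded into the 1/0.7
    overall scaling.
    """

    g: float = 9.80665              # gravitational acceleration, m/s^2
    pa_per_mmHg: float = 133.322    # unit conversion, Pa per mmHg
    height_factor: float = 0.48     # effective path length d = 0.48 * height
    denom: float = 1.4              # kinetic coefficient denominator
    scale: float = 0.7              # overall empirical scaling of the bracket

    def __post_init__(self) -> None:
        if not math.isclose(self.denom, 2.0 * self.scale):
            raise ValueError("denom must equal 2 * scale")


CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject parameters of the BP model.

    Parameters
    ----------
    height : float
        Subject height in metres; proxy for the heart-to-wrist path length.
    blood_density : float
        Blood density in kg/m^3 (population average 1035).
    arm_offset : float
        Vertical offset of the wrist *below* heart level, in metres.
        0 means the wrist is at heart level; positive values raise the
        estimated pressure through the hydrostatic term.
    correction_B : float
        Fixed additive correction constant in mmHg (about 40).
    """

    height: float
    blood_density: float = 1035.0
    arm_offset: float = 0.0
    correction_B: float = 40.0

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise DomainError(f"height must be > 0 m, got {self.height}")
        if not (self.blood_density > 0):
            raise DomainError(
                f"blood_density must be > 0 kg/m^3, got {self.blood_density}"
            )
        if not math.isfinite(self.correction_B):
            raise DomainError("correction_B must be finite")


@dataclass(frozen=True)
class BPEstimate:
    """One beat's estimated systolic/diastolic pressure, in mmHg."""

    beat_time: float
    sbp: float
    dbp: float


def coefficient_A(
    subject: SubjectProfile, constants: ModelConstants = CONSTANTS
) -> float:
    """Kinetic coefficient ``A = (0.48 * height)**2 * rho / 1.4`` in kg/m.

    ``A / PTT**2`` is the kinetic pressure contribution in pascals.
    """
    d = constants.height_factor * subject.height
    return d * d * subject.blood_density / constants.denom


def _hydrostatic_pa(
    subject: SubjectProfile, constants: ModelConstants = CONSTANTS
) -> float:
    """Hydrostatic term rho*g*h / 0.7 in pascals (shares the 1/0.7 scaling)."""
    return (
        subject.blood_density * constants.g * subject.arm_offset / constants.scale
    )


def _bp_from_ptt(
    ptt: float, subject: SubjectProfile, constants: ModelConstants
) -> float:
    if not (ptt > 0):
        raise DomainError(f"PTT must be > 0 s, got {ptt}")
    A = coefficient_A(subject, constants)
    pa = A / (ptt * ptt) + _hydrostatic_pa(subject, constants)
    return pa / constants.pa_per_mmHg + subject.correction_B


def estimate_bp(
    ptt1: float,
    ptt2: float,
    subject: SubjectProfile,
    beat_time: float = 0.0,
    constants: ModelConstants = CONSTANTS,
) -> BPEstimate:
    """Convert one beat's (PTT1, PTT2) to (SBP, DBP) in mmHg.

    PTT1 must precede PTT2 (the negative pulse-wave extremum arrives before
    the positive one); model monotonicity then guarantees SBP > DBP.
    """
    if not (0 < ptt1 < ptt2):
        raise DomainError(f"require 0 < ptt1 < ptt2, got ({ptt1}, {ptt2})")
    sbp = _bp_from_ptt(ptt1, subject, constants)
    dbp = _bp_from_ptt(ptt2, subject, constants)
    return BPEstimate(beat_time=beat_time, sbp=sbp, dbp=dbp)


def bp_asymptote(
    subject: SubjectProfile, constants: ModelConstants = CONSTANTS
) -> float:
    """Pressure approached as PTT → ∞: B plus the hydrostatic term, mmHg."""
    return (
        subject.correction_B
        + _hydrostatic_pa(subject, constants) / constants.pa_per_mmHg
    )


def invert_bp(
    bp: float, subject: SubjectProfile, constants: ModelConstants = CONSTANTS
) -> float:
    """Analytic inverse: the PTT (s) whose model pressure equals ``bp`` mmHg.

    Defined only above the model's asymptotic pressure
    ``B + rho*g*h/(0.7*133.322)``.
    """
    asymptote = bp_asymptote(subject, constants)
    if bp <= asymptote:
        raise DomainError(
            f"bp={bp} mmHg is at or below the model asymptote "
            f"{asymptote:.6g} mmHg; no finite PTT exists"
        )
    A = coefficient_A(subject, constants)
    kinetic_pa = (bp - subject.correction_B) * constants.pa_per_mmHg - _hydrostatic_pa(
        subject, constants
    )
    return math.sqrt(A / kinetic_pa)


def calibrate_B(
    ptt: float,
    reference_bp: float,
    subject: SubjectProfile,
    constants: ModelConstants = CONSTANTS,
) -> float:
    """One-point calibration of the correction constant B.

    Returns the B (mmHg) for which the model reproduces ``reference_bp``
    exactly at the observed ``ptt``; all other subject parameters are kept.
    """
    if not (ptt > 0):
        raise DomainError(f"PTT must be > 0 s, got {ptt}")
    A = coefficient_A(subject, constants)
    pa = A / (ptt * ptt) + _hydrostatic_pa(subject, constants)
    return reference_bp - pa / constants.pa_per_mmHg
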