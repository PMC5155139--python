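"""Lever-model bite force, bite force quotient, and beam-theory bending
strength for canines and mandibular cross-sections.

The dry-skull lever model treats the jaw as a third-class lever about the
temporomandibular joint (TMJ): temporalis and masseter+pterygoid forces
(muscle cross-sectional area x a constant 300 kPa muscle stress) act at
their lever arms, and the bite force at a tooth is the summed moment
divided by the out-lever to that bite point, doubled for bilateral biting:

    F = 2 (T t + M m) / o

The bite force quotient (BFQ) size-corrects force via the residual of a
log10 force ~ log10 mass regression over a comparative sample, scaled so
that a taxon on the regression line scores 100.

Teeth and mandibular corpora are modelled as solid elliptical beams; the
section modulus about the axis perpendicular to bending is
Z = pi * d_perp * d_bend^2 / 32, and bending strength is Z over the load
arm (canine crown height, or distance from an interdental gap to the
condyle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .allometry import LogLogRegression

__all__ = [
    "SkullLeverMeasurements",
    "BiteForceEstimate",
    "BeamSection",
    "BendingStrengths",
    "MANDIBLE_GAP_ORDER",
    "muscle_force",
    "bite_force",
    "bite_force_quotient",
    "elliptical_section_modulus",
    "canine_bending_strength",
    "mandible_force_profile",
]

#: anterior -> posterior interdental gaps at which the mandibular corpus
#: is sectioned (metatherian dental formula)
MANDIBLE_GAP_ORDER = ("canine", "p2-p3", "p3-m1", "m1-m2", "m2-3", "post m4")

DEFAULT_MUSCLE_STRESS_KPA = 300.0


@dataclass
class SkullLeverMeasurements:
    """One side's muscle areas, lever arms and out-levers about the TMJ."""

    specimen_id: str
    temporalis_area_mm2: float
    masseter_pterygoid_area_mm2: float
    temporalis_arm_mm: float
    masseter_arm_mm: float
    outlever_canine_mm: float
    outlever_m1_mm: float
    side: str = "left"

    def __post_init__(self):
        vals = (
            self.temporalis_area_mm2,
            self.masseter_pterygoid_area_mm2,
            self.temporalis_arm_mm,
            self.masseter_arm_mm,
            self.outlever_canine_mm,
            self.outlever_m1_mm,
        )
        if any(v <= 0 for v in vals[2:]):
            raise ValueError("lever arms and out-levers must be positive")
        if any(v < 0 for v in vals[:2]):
            raise ValueError("muscle areas must be non-negative")
        if self.outlever_canine_mm <= self.outlever_m1_mm:
            raise ValueError(
                "canine out-lever must exceed the first-molar out-lever "
                "(the canine is more anterior)"
            )


@dataclass
class BiteForceEstimate:
    canine_force_N: float
    molar_force_N: float
    bfq: float | None = None
    muscle_stress_kPa: float = DEFAULT_MUSCLE_STRESS_KPA

    def __post_init__(self):
        if self.molar_force_N < self.canine_force_N:
            raise ValueError("molar force cannot be below canine force")


@dataclass
class BeamSection:
    """Elliptical cross-section (two orthogonal diameters) plus a load arm.

    For the canine, the arm is crown height; for a mandibular gap, the
    distance from the section to the condyle.
    """

    location: str
    d_ap_mm: float  # anteroposterior diameter
    d_ml_mm: float  # mediolateral diameter
    arm_mm: float

    def __post_init__(self):
        if self.d_ap_mm <= 0 or self.d_ml_mm <= 0:
            raise ValueError("section diameters must be positive")
        if self.arm_mm <= 0:
            raise ValueError("load arm must be positive")


@dataclass
class BendingStrengths:
    """Section moduli (mm^3) and per-arm bending strengths (mm^2).

    zx resists dorsoventral bending (bending in the parasagittal plane,
    about the mediolateral axis); zy resists mediolateral bending.
    zx/zy near 1 indicates a round, torsion-resistant section.
    """

    location: str
    zx: float
    zy: float
    zx_over_arm: float
    zy_over_arm: float
    zx_over_zy: float


def muscle_force(area_mm2: float,
                 stress_kPa: float = DEFAULT_MUSCLE_STRESS_KPA) -> float:
    """Muscle force (N) from cross-sectional area (mm^2) at constant
    muscle stress (kPa): 300 kPa = 0.3 N/mm^2."""
    if area_mm2 < 0:
        raise ValueError("muscle area cannot be negative")
    if stress_kPa <= 0:
        raise ValueError("muscle stress must be positive")
    return area_mm2 * stress_kPa * 1e-3


def bite_force(meas: SkullLeverMeasurements, bite_point: str = "canine",
               stress_kPa: float = DEFAULT_MUSCLE_STRESS_KPA,
               bilateral: bool = True) -> float:
    """Bite force (N) at the canine tip or first-molar centre.

    Sum of the temporalis and masseter moments about the TMJ divided by
    the out-lever, doubled for bilateral biting unless ``bilateral=False``
    (which returns the one-sided value).
    """
    if bite_point not in ("canine", "m1"):
        raise ValueError(f"unknown bite point {bite_point!r}; use 'canine' or 'm1'")
    T = muscle_force(meas.temporalis_area_mm2, stress_kPa)
    M = muscle_force(meas.masseter_pterygoid_area_mm2, stress_kPa)
    o = meas.outlever_canine_mm if bite_point == "canine" else meas.outlever_m1_mm
    unilateral = (T * meas.temporalis_arm_mm + M * meas.masseter_arm_mm) / o
    return 2.0 * unilateral if bilateral else unilateral


def bite_force_estimate(meas: SkullLeverMeasurements,
                        stress_kPa: float = DEFAULT_MUSCLE_STRESS_KPA) -> BiteForceEstimate:
    """Canine and molar bite forces for one measurement set."""
    return BiteForceEstimate(
        canine_force_N=bite_force(meas, "canine", stress_kPa),
        molar_force_N=bite_force(meas, "m1", stress_kPa),
        muscle_stress_kPa=stress_kPa,
    )


def bite_force_quotient(mass_kg: float, force_N: float,
                        comparative: Sequence[tuple[float, float]]) -> float:
    """Size-corrected relative bite force.

    Fits log10(force) ~ log10(mass) over the comparative (mass, force)
    table and returns 100 x 10**(observed - predicted log10 force).  A
    query on the regression line scores exactly 100; the geometric mean
    of training-set BFQs is 100 because OLS residuals sum to zero in log
    space.
    """
    if mass_kg <= 0 or force_N <= 0:
        raise ValueError("query mass and force must be positive")
    comp = np.asarray(comparative, dtype=float)
    if comp.ndim != 2 or comp.shape[1] != 2 or comp.shape[0] < 3:
        raise ValueError("comparative table must be n x 2 with n >= 3")
    if np.ptp(comp[:, 0]) == 0:
        raise ValueError("degenerate regression: all comparative masses equal")
    reg = LogLogRegression(response_units="N").fit(comp[:, 0], comp[:, 1])
    resid = math.log10(force_N) - reg.predict_log10([mass_kg])[0]
    return 100.0 * 10.0 ** resid


def elliptical_section_modulus(d_bend_mm: float, d_perp_mm: float) -> float:
    """Section modulus (mm^3) of a solid ellipse for bending along
    ``d_bend``: Z = pi * d_perp * d_bend^2 / 32."""
    if d_bend_mm <= 0 or d_perp_mm <= 0:
        raise ValueError("diameters must be positive")
    return math.pi * d_perp_mm * d_bend_mm**2 / 32.0


def _section_strengths(section: BeamSection) -> BendingStrengths:
    # zx: bending in the anteroposterior plane -> depth is d_ap
    zx = elliptical_section_modulus(section.d_ap_mm, section.d_ml_mm)
    zy = elliptical_section_modulus(section.d_ml_mm, section.d_ap_mm)
    return BendingStrengths(
        location=section.location,
        zx=zx,
        zy=zy,
        zx_over_arm=zx / section.arm_mm,
        zy_over_arm=zy / section.arm_mm,
        zx_over_zy=zx / zy,
    )


def canine_bending_strength(section: BeamSection) -> BendingStrengths:
    """Anteroposterior (Sx) and mediolateral (Sy) bending strengths of a
    canine modelled as a solid elliptical beam loaded at the crown tip."""
    if section.location != "canine":
        raise ValueError("canine_bending_strength expects a canine section")
    return _section_strengths(section)


def mandible_force_profile(sections: Iterable[BeamSection]) -> list[BendingStrengths]:
    """Per-gap Zx/L, Zy/L and Zx/Zy along the mandibular corpus.

    Sections must arrive in anterior -> posterior order with no duplicate
    locations; the output order matches the input and is suitable for
    plotting as a mandibular force profile.
    """
    secs = list(sections)
    locs = [s.location for s in secs]
    if len(set(locs)) != len(locs):
        raise ValueError("duplicate section locations in mandible profile")
    known = [l for l in locs if l in MANDIBLE_GAP_ORDER]
    ranks = [MANDIBLE_GAP_ORDER.index(l) for l in known]
    if ranks != sorted(ranks):
        raise ValueError(
            "sections must be ordered anterior to posterior "
            f"({' -> '.join(MANDIBLE_GAP_ORDER)})"
        )
    return [_section_strengths(s) for s in secs]
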