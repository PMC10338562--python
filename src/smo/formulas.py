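"""Closed-form estimators from resting and demographic inputs.

These are the population-regression baselines of the pipeline: the Whyte
age/sex equation estimating maximal heart rate,

    HRmax = 202 - 0.55 * age   (males)
    HRmax = 216 - 1.09 * age   (females)

and the Jurca non-exercise equation estimating VO2max in ml·kg⁻¹·min⁻¹ from
sex, age, body-mass index, resting heart rate and a self-reported
physical-activity score (PAS),

    VO2max = 3.5 * (18.07 + 2.77*sex - 0.1*age - 0.17*BMI - 0.03*RHR + PAS)

with sex coded 1 for males and 0 for females.  Agreement between an
estimator and a measurement is quantified throughout by the relative error

    delta = 100 * |experimental - predicted| / experimental   (%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np

__all__ = [
    "Subject",
    "whyte_hrmax",
    "jurca_vo2max",
    "relative_error",
    "evaluate_estimators",
    "PAS_CATEGORIES",
    "HRMAX_FORMULAS",
    "VO2MAX_FORMULAS",
]

#: Physical-activity score by self-reported category, following the original
#: non-exercise fitness model's questionnaire coding.  The study cohorts were
#: physically active at the highest level (>= 3 h of vigorous exercise per
#: week), i.e. category 'vigorous_high'.
PAS_CATEGORIES: Dict[str, float] = {
    "sedentary": 0.00,
    "light": 0.32,
    "moderate": 1.06,
    "vigorous_moderate": 1.76,
    "vigorous_high": 3.03,
}


@dataclass(frozen=True)
class Subject:
    """Demographic and resting characteristics of one participant."""

    id: str
    sex: str  # 'male' | 'female'
    age: float  # years
    bmi: float  # kg/m^2
    rhr: float  # resting heart rate, bpm
    pas: Optional[float] = None  # physical-activity score (dimensionless)
    mass_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 0 and self.age != 0:  # age 0 allowed as formula boundary
            raise ValueError("age must be non-negative")
        if self.bmi <= 0:
            raise ValueError("BMI must be positive")
        if self.rhr <= 0:
            raise ValueError("resting HR must be positive")


def whyte_hrmax(subject: Subject) -> float:
    """Age- and sex-specific maximal heart rate estimate (bpm)."""
    if subject.sex == "male":
        return 202.0 - 0.55 * subject.age
    return 216.0 - 1.09 * subject.age


def jurca_vo2max(subject: Subject, per_kg: bool = True) -> float:
    """Non-exercise VO2max estimate.

    Returns ml·kg⁻¹·min⁻¹ by default; with ``per_kg=False`` converts to
    L/min, which requires ``subject.mass_kg``.
    """
    if subject.pas is None:
        raise ValueError("subject.pas (physical-activity score) is required")
    sex = 1.0 if subject.sex == "male" else 0.0
    rel = 3.5 * (18.07 + 2.77 * sex - 0.1 * subject.age - 0.17 * subject.bmi
                 - 0.03 * subject.rhr + subject.pas)
    if per_kg:
        return rel
    if subject.mass_kg is None:
        raise ValueError("mass_kg required to convert ml/kg/min to L/min")
    return rel * subject.mass_kg / 1000.0


def relative_error(experimental: float, predicted: float) -> float:
    """Relative error in percent: ``100 * |exp - pred| / exp``."""
    if experimental == 0:
        raise ZeroDivisionError("experimental value must be non-zero")
    return 100.0 * abs(experimental - predicted) / abs(experimental)


#: Extensible registries of resting-parameter estimators, keyed by name.
HRMAX_FORMULAS: Dict[str, Callable[[Subject], float]] = {"whyte": whyte_hrmax}
VO2MAX_FORMULAS: Dict[str, Callable[[Subject], float]] = {
    "jurca": lambda s: jurca_vo2max(s, per_kg=False),
    "jurca_per_kg": jurca_vo2max,
}


def evaluate_estimators(subjects: Sequence[Subject], measured: Sequence[float],
                        formulas: Optional[Dict[str, Callable[[Subject], float]]] = None,
                        ) -> Dict[str, Dict[str, float]]:
    """Mean and SD of relative errors of each registered formula on a cohort.

    ``measured`` holds the experimental value of the quantity each formula
    estimates (same units as the formula output), one per subject.
    """
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    if len(subjects) != len(measured):
        raise ValueError("subjects and measured must have equal length")
    formulas = formulas if formulas is not None else HRMAX_FORMULAS
    out: Dict[str, Dict[str, float]] = {}
    for name, f in formulas.items():
        deltas = np.array([relative_error(m, f(s))
                           for s, m in zip(subjects, measured)])
        out[name] = {
            "mean_delta_pct": float(deltas.mean()),
            "sd_delta_pct": float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
            "n": int(deltas.size),
        }
    return out
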