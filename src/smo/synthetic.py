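"""Synthetic cohorts with known ground truth.

No raw recordings of the original cohorts were deposited, so validation of
the pipeline rests on model-faithful synthetic subjects: demographics are
drawn to match the reference cohort's moments (young physically active
males, 23.5 ± 2.0 years, BMI 23.9 ± 3.2 kg/m²), kinetic parameters from
documented physiological ranges, and the tests themselves are simulated
from the first-order response model with additive Gaussian measurement
noise.  Every generated subject carries its full ground truth — the
parameter triples, the true maximal heart rate and the model VO2max — so
estimator and pipeline errors can be measured exactly.

The true HRmax is drawn as the Whyte estimate plus a subject-specific
offset, so the estimated and true HRmax differ the way they do in real
cohorts and tests can probe the impact of HRmax mis-estimation.

What the generator does *not* emulate: the VO2 slow component, heart-rate
deflection above the second ventilatory threshold, cardiovascular drift,
or breath-by-breath sampling irregularity (available schematically behind
``irregular_sampling``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .formulas import PAS_CATEGORIES, Subject, whyte_hrmax
from .kinetics import KineticsParams, simulate
from .preprocessing import PhysioSeries
from .protocol import WorkloadProtocol, validation_protocol

__all__ = ["CohortRanges", "SyntheticSubjectTruth", "sample_cohort",
           "generate_test"]

DEFAULT_NOISE_SD_HR = 2.0      # bpm
DEFAULT_NOISE_SD_VO2 = 0.08    # L/min


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges/moments for synthetic subjects.

    Demographic moments default to the reference cohort; kinetic-parameter
    ranges are plausible ranges for young active adults on a cycle
    ergometer (HR gain 0.3–0.6 bpm/W, VO2 gain ~10 ml·min⁻¹/W i.e.
    0.009–0.012 L·min⁻¹/W, time decays 25–60 s).
    """

    age_mean: float = 23.5
    age_sd: float = 2.0
    bmi_mean: float = 23.9
    bmi_sd: float = 3.2
    rhr_range: Tuple[float, float] = (50.0, 70.0)
    height_mean_m: float = 1.80
    height_sd_m: float = 0.06
    pas: float = PAS_CATEGORIES["vigorous_high"]
    k_hr_range: Tuple[float, float] = (0.3, 0.6)
    tau_hr_range: Tuple[float, float] = (25.0, 60.0)
    x0_hr_range: Tuple[float, float] = (55.0, 80.0)
    k_vo2_range: Tuple[float, float] = (0.009, 0.012)
    tau_vo2_range: Tuple[float, float] = (25.0, 50.0)
    x0_vo2_range: Tuple[float, float] = (0.25, 0.45)
    hrmax_offset_sd: float = 7.0
    noise_sd_hr: float = DEFAULT_NOISE_SD_HR
    noise_sd_vo2: float = DEFAULT_NOISE_SD_VO2

    def __post_init__(self) -> None:
        for name in ("rhr_range", "k_hr_range", "tau_hr_range", "x0_hr_range",
                     "k_vo2_range", "tau_vo2_range", "x0_vo2_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"inverted range {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class SyntheticSubjectTruth:
    """One synthetic subject and everything needed to grade predictions."""

    subject: Subject
    hr_params: KineticsParams
    vo2_params: KineticsParams
    true_hrmax: float
    true_vo2max: float
    noise_sd_hr: float
    noise_sd_vo2: float
    protocol_name: str = "validation"

    def to_dict(self) -> dict:
        return {
            "subject": {
                "id": self.subject.id, "sex": self.subject.sex,
                "age": self.subject.age, "bmi": self.subject.bmi,
                "rhr": self.subject.rhr, "pas": self.subject.pas,
                "mass_kg": self.subject.mass_kg,
            },
            "hr_params": {"K": self.hr_params.K, "tau": self.hr_params.tau,
                          "X0": self.hr_params.X0},
            "vo2_params": {"K": self.vo2_params.K, "tau": self.vo2_params.tau,
                           "X0": self.vo2_params.X0},
            "true_hrmax_bpm": self.true_hrmax,
            "true_vo2max_L_min": self.true_vo2max,
            "noise_sd_hr": self.noise_sd_hr,
            "noise_sd_vo2": self.noise_sd_vo2,
            "protocol_name": self.protocol_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSubjectTruth":
        return cls(
            subject=Subject(**d["subject"]),
            hr_params=KineticsParams(**d["hr_params"], variable="HR"),
            vo2_params=KineticsParams(**d["vo2_params"], variable="VO2"),
            true_hrmax=d["true_hrmax_bpm"],
            true_vo2max=d["true_vo2max_L_min"],
            noise_sd_hr=d["noise_sd_hr"], noise_sd_vo2=d["noise_sd_vo2"],
            protocol_name=d.get("protocol_name", "validation"),
        )


def _hr_crossing_time(hr_params: KineticsParams, protocol: WorkloadProtocol,
                      target: float, horizon_s: float = 7200.0) -> float:
    """First 1-s grid time at which the noise-free HR reaches ``target``."""
    grid = np.arange(0.0, horizon_s + 1.0)
    sim = simulate(hr_params, protocol, None, grid)
    above = sim.values >= target
    if not np.any(above):
        raise RuntimeError(
            f"HR never reaches {target:.1f} bpm within {horizon_s:.0f} s "
            f"(K={hr_params.K:.3g}, X0={hr_params.X0:.3g})")
    return float(grid[int(np.argmax(above))])


def true_vo2max_for(hr_params: KineticsParams, vo2_params: KineticsParams,
                    true_hrmax: float,
                    protocol: Optional[WorkloadProtocol] = None) -> float:
    """Model VO2 at the time noise-free HR first reaches the true HRmax.

    This is the construction defining a synthetic subject's true VO2max;
    it is re-derivable from the stored parameters at any time.
    """
    prot = protocol if protocol is not None else validation_protocol()
    t_max = _hr_crossing_time(hr_params, prot, true_hrmax)
    return float(simulate(vo2_params, prot, None,
                          np.array([0.0, t_max])).values[-1])


def sample_cohort(n: int, seed: int,
                  ranges: Optional[CohortRanges] = None,
                  protocol: Optional[WorkloadProtocol] = None,
                  ) -> List[SyntheticSubjectTruth]:
    """Draw ``n`` synthetic subjects, reproducibly by ``seed``.

    ``protocol`` (default: the validation builder with an open-ended ramp)
    defines the maximal test on which each subject's true VO2max is realised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges if ranges is not None else CohortRanges()
    prot = protocol if protocol is not None else validation_protocol()
    rng = np.random.default_rng(seed)
    cohort: List[SyntheticSubjectTruth] = []
    for i in range(n):
        age = float(np.clip(rng.normal(ranges.age_mean, ranges.age_sd), 18, 45))
        bmi = float(np.clip(rng.normal(ranges.bmi_mean, ranges.bmi_sd), 17, 35))
        rhr = float(rng.uniform(*ranges.rhr_range))
        height = float(rng.normal(ranges.height_mean_m, ranges.height_sd_m))
        subject = Subject(id=f"SYN{i + 1:02d}", sex="male", age=age, bmi=bmi,
                          rhr=rhr, pas=ranges.pas,
                          mass_kg=round(bmi * height ** 2, 1))
        hr_params = KineticsParams(
            K=float(rng.uniform(*ranges.k_hr_range)),
            tau=float(rng.uniform(*ranges.tau_hr_range)),
            X0=float(rng.uniform(*ranges.x0_hr_range)), variable="HR")
        vo2_params = KineticsParams(
            K=float(rng.uniform(*ranges.k_vo2_range)),
            tau=float(rng.uniform(*ranges.tau_vo2_range)),
            X0=float(rng.uniform(*ranges.x0_vo2_range)), variable="VO2")
        true_hrmax = whyte_hrmax(subject) + float(
            rng.normal(0.0, ranges.hrmax_offset_sd))
        true_hrmax = max(true_hrmax, hr_params.X0 + 40.0)
        vo2max = true_vo2max_for(hr_params, vo2_params, true_hrmax, prot)
        cohort.append(SyntheticSubjectTruth(
            subject=subject, hr_params=hr_params, vo2_params=vo2_params,
            true_hrmax=true_hrmax, true_vo2max=vo2max,
            noise_sd_hr=ranges.noise_sd_hr, noise_sd_vo2=ranges.noise_sd_vo2,
            protocol_name=prot.name))
    return cohort


def generate_test(truth: SyntheticSubjectTruth,
                  protocol: Optional[WorkloadProtocol] = None,
                  mode: str = "maximal", seed: int = 0,
                  recovery_duration_s: float = 300.0,
                  irregular_sampling: bool = False,
                  ) -> Tuple[PhysioSeries, PhysioSeries, WorkloadProtocol]:
    """Simulate one incremental test for a synthetic subject.

    ``mode='maximal'`` runs the ramp until the noise-free HR reaches the
    subject's true HRmax; ``mode='submaximal_80'`` stops at 80% of the
    Whyte-estimated HRmax (the prospective termination rule).  A constant
    50 W recovery follows in both modes.  Independent Gaussian noise is
    added per sample and the record is emitted at 1 Hz with phase labels.

    The HR and VO2 noise streams are seeded separately from ``seed``, so a
    submaximal record is an exact temporal prefix of the maximal one (same
    truth, same seed) up to its earlier cut.
    """
    if mode not in ("maximal", "submaximal_80"):
        raise ValueError(f"unknown mode {mode!r}")
    base = protocol if protocol is not None else validation_protocol()
    if base.end_s is not None:
        raise ValueError("base protocol must have an open-ended ramp")
    if mode == "maximal":
        target = truth.true_hrmax
    else:
        target = 0.8 * whyte_hrmax(truth.subject)
    ramp = base.ramp_segment()
    t_cut = _hr_crossing_time(truth.hr_params, base, target)
    if t_cut <= ramp.start_s:
        raise RuntimeError(
            f"HR target {target:.1f} bpm reached before the ramp; "
            "subject resting HR too close to the target")
    prot = base.truncate_ramp(t_cut + 0.5, recovery_duration_s)
    grid = np.arange(0.0, float(prot.end_s))
    rng_hr = np.random.default_rng([seed, 11])
    rng_vo2 = np.random.default_rng([seed, 23])
    out = []
    for params, noise_sd, rng, floor in (
        (truth.hr_params, truth.noise_sd_hr, rng_hr, 20.0),
        (truth.vo2_params, truth.noise_sd_vo2, rng_vo2, 0.05),
    ):
        clean = simulate(params, prot, None, grid).values
        noisy = clean + rng.normal(0.0, noise_sd, grid.size) if noise_sd > 0 \
            else clean.copy()
        times = grid
        if irregular_sampling:
            jitter = rng.uniform(-0.3, 0.3, grid.size)
            jitter[0] = jitter[-1] = 0.0
            times = np.sort(grid + jitter)
        ser = PhysioSeries(times, np.maximum(noisy, floor),
                           params.variable).label_phases(prot)
        out.append(ser)
    return out[0], out[1], prot
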