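"""The submaximal VO2max prediction pipeline (SMO).

Given a submaximal incremental test record (warm-up, ramp terminated around
80% of the estimated maximal heart rate, recovery), the pipeline:

1. estimates the subject's maximal heart rate from the Whyte age/sex
   equation (or uses a supplied target);
2. fits the first-order kinetics model to the recorded HR;
3. extrapolates the fitted HR model beyond the recorded ramp end, with the
   ramp continued at identical step increments, on a 1-s grid until the
   model HR reaches the HRmax target to within 0.1 bpm — that time is
   ``t_HRmax_model``;
4. fits the same model to the recorded VO2 under the identical workload;
5. extrapolates the fitted VO2 model to ``t_HRmax_model``; the value there
   is the predicted VO2max.

The extrapolation restarts from the last smoothed observed value at the
recorded ramp end rather than from the model trajectory, so any model-data
offset at the splice point does not shift ``t_HRmax_model``; the offset is
reported as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .estimation import (DEFAULT_EMBEDDING_WIDTH, KineticsModel,
                         KineticsResults)
from .formulas import Subject, whyte_hrmax
from .kinetics import KineticsParams, SimulatedResponse, simulate
from .preprocessing import DEFAULT_MA_WINDOW, PhysioSeries
from .protocol import WorkloadProtocol

__all__ = [
    "ExtrapolationResult",
    "SMOResults",
    "SubmaximalVO2Model",
    "extrapolate_to_hrmax",
]

#: Stopping accuracy of the HR extrapolation (bpm).
HR_ACCURACY_BPM = 0.1
#: Extrapolation time step (s).
EXTRAPOLATION_STEP_S = 1.0
DEFAULT_HORIZON_S = 7200.0


class ExtrapolationError(RuntimeError):
    """Raised when the fitted model cannot be extrapolated to the target."""


class PipelineError(RuntimeError):
    """A stage of the prediction pipeline failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class ExtrapolationResult:
    """Model trajectory extrapolated on a 1-s grid up to the HRmax target."""

    times: np.ndarray
    values: np.ndarray
    t_hrmax_model: float
    reached: bool
    hrmax_target: float

    def value_at(self, t: float) -> float:
        i = int(round(t - self.times[0]))
        if i < 0 or i >= self.times.size:
            raise ValueError(f"t={t} outside extrapolation grid")
        return float(self.values[i])


def extrapolate_to_hrmax(params: KineticsParams, protocol: WorkloadProtocol,
                         hrmax_target: float, x_start: float, t_start: float,
                         horizon_s: float = DEFAULT_HORIZON_S,
                         refine_bisection: bool = False) -> ExtrapolationResult:
    """Simulate the fitted HR model forward until it reaches the target.

    The protocol must have an open-ended (extended) ramp.  The crossing is
    detected on the 1-s grid with the 0.1-bpm stopping accuracy; with
    ``refine_bisection`` the crossing time is refined inside the final
    second (reported in place of the grid time, trajectory grid unchanged).
    If the target is not reached within ``horizon_s`` the result carries
    ``reached=False`` with the full horizon trajectory.
    """
    if params.K <= 0 or params.tau <= 0:
        raise ExtrapolationError(
            f"cannot extrapolate with K={params.K:.4g}, tau={params.tau:.4g}")
    grid = t_start + np.arange(0.0, horizon_s + EXTRAPOLATION_STEP_S,
                               EXTRAPOLATION_STEP_S)
    sim = simulate(params, protocol, x_start, grid)
    above = sim.values >= hrmax_target - HR_ACCURACY_BPM
    if not np.any(above):
        return ExtrapolationResult(grid, sim.values, float(grid[-1]), False,
                                   hrmax_target)
    i = int(np.argmax(above))
    t_cross = float(grid[i])
    if refine_bisection and i > 0:
        lo, hi = float(grid[i - 1]), t_cross
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            v = simulate(params, protocol, float(sim.values[i - 1]),
                         np.array([lo, mid])).values[-1]
            if v >= hrmax_target - HR_ACCURACY_BPM:
                hi = mid
            else:
                lo = mid
        t_cross = hi
    keep = grid <= grid[i]
    return ExtrapolationResult(grid[keep], sim.values[keep], t_cross, True,
                               hrmax_target)


@dataclass
class SMOResults:
    """Results of the submaximal VO2max prediction.

    ``vo2max_predicted`` is in L/min, read from the extrapolated VO2
    trajectory at ``t_hrmax_model``.  ``splice_offset_bpm`` is the model
    minus data offset of the HR fit at the extrapolation start — a
    diagnostic for fit quality at the splice point.
    """

    hrmax_estimate: float
    hr_fit: KineticsResults
    vo2_fit: KineticsResults
    t_hrmax_model: float
    vo2max_predicted: float
    reached: bool
    t_ramp_end: float
    hr_extrapolation: ExtrapolationResult
    vo2_extrapolation: SimulatedResponse
    splice_offset_bpm: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hrmax_estimate_bpm": self.hrmax_estimate,
            "t_hrmax_model_s": self.t_hrmax_model,
            "vo2max_predicted_L_min": self.vo2max_predicted,
            "reached": self.reached,
            "t_ramp_end_s": self.t_ramp_end,
            "splice_offset_bpm": self.splice_offset_bpm,
            "hr_fit": self.hr_fit.to_dict(),
            "vo2_fit": self.vo2_fit.to_dict(),
            "config": dict(self.config),
        }

    def extrapolation_table(self):
        """Per-second extrapolated HR and VO2 as a DataFrame."""
        import pandas as pd
        n = min(self.hr_extrapolation.times.size, self.vo2_extrapolation.times.size)
        return pd.DataFrame({
            "time_s": self.hr_extrapolation.times[:n],
            "hr_bpm": self.hr_extrapolation.values[:n],
            "vo2_L_min": self.vo2_extrapolation.values[:n],
        })

    def plot(self, hr_series=None, vo2_series=None):
        """Extrapolated HR and VO2 trajectories, optionally over the data."""
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
        if hr_series is not None:
            ax1.plot(hr_series.times, hr_series.values, ".", ms=2,
                     color="0.6", label="recorded HR")
        ax1.plot(self.hr_extrapolation.times, self.hr_extrapolation.values,
                 "-", label="extrapolated HR")
        ax1.axhline(self.hrmax_estimate, ls="--", color="gray",
                    label="HRmax target")
        ax1.set_ylabel("HR (bpm)")
        ax1.legend(frameon=False)
        if vo2_series is not None:
            ax2.plot(vo2_series.times, vo2_series.values, ".", ms=2,
                     color="0.6", label="recorded VO2")
        ax2.plot(self.vo2_extrapolation.times, self.vo2_extrapolation.values,
                 "-", label="extrapolated VO2")
        ax2.plot(self.t_hrmax_model, self.vo2max_predicted, "r*", ms=10,
                 label=f"predicted VO2max = {self.vo2max_predicted:.2f} L/min")
        ax2.axvline(self.t_hrmax_model, ls="--", color="gray")
        ax2.set_xlabel("time (s)")
        ax2.set_ylabel("VO2 (L/min)")
        ax2.legend(frameon=False)
        return fig

    def summary(self) -> str:
        lines = [
            "Submaximal VO2max prediction (SMO)",
            "=" * 52,
            f"HRmax target            : {self.hrmax_estimate:.1f} bpm",
            f"recorded ramp end       : {self.t_ramp_end:.0f} s",
            f"t_HRmax_model           : {self.t_hrmax_model:.0f} s"
            + ("" if self.reached else "  (horizon cap, target not reached)"),
            f"predicted VO2max        : {self.vo2max_predicted:.3f} L/min",
            f"HR splice offset        : {self.splice_offset_bpm:+.2f} bpm",
            "",
            self.hr_fit.summary(),
            "",
            self.vo2_fit.summary(),
        ]
        return "\n".join(lines)


class SubmaximalVO2Model:
    """Model object for the six-step submaximal VO2max prediction.

    Parameters
    ----------
    hr_series, vo2_series : PhysioSeries
        Preprocessed (1 Hz resampled, moving-average smoothed) recordings of
        the submaximal test, covering warm-up, ramp and ideally recovery.
    protocol : WorkloadProtocol
        Workload schedule of the recorded test (ramp truncated where the
        test was stopped).
    subject : Subject, optional
        Needed unless an explicit ``hrmax_target`` is given.
    vo2_protocol : WorkloadProtocol, optional
        Separate schedule for the VO2 fit when the VO2 record has its own
        timing (used by the truncation study's spliced series); the ramp and
        its increments are identical, so extrapolation workload is unchanged.
    hrmax_target : float, optional
        Overrides the Whyte estimate (e.g. a measured HRmax).
    ma_window : int
        Moving-average window that was applied to the series; the workload
        regressor is smoothed identically during fitting.
    """

    def __init__(self, hr_series: PhysioSeries, vo2_series: PhysioSeries,
                 protocol: WorkloadProtocol, subject: Optional[Subject] = None,
                 vo2_protocol: Optional[WorkloadProtocol] = None,
                 hrmax_target: Optional[float] = None,
                 estimator: str = "derivative_regression",
                 embedding_width: int = DEFAULT_EMBEDDING_WIDTH,
                 ma_window: int = DEFAULT_MA_WINDOW,
                 include_baseline: bool = False,
                 horizon_s: float = DEFAULT_HORIZON_S,
                 refine_bisection: bool = False) -> None:
        if hrmax_target is None and subject is None:
            raise ValueError("either subject or hrmax_target is required")
        self.hr_series = hr_series
        self.vo2_series = vo2_series
        self.protocol = protocol
        self.vo2_protocol = vo2_protocol if vo2_protocol is not None else protocol
        self.subject = subject
        self.hrmax_target = hrmax_target
        self.estimator = estimator
        self.embedding_width = embedding_width
        self.ma_window = ma_window
        self.include_baseline = include_baseline
        self.horizon_s = horizon_s
        self.refine_bisection = refine_bisection

    @classmethod
    def from_raw(cls, hr_raw: PhysioSeries, vo2_raw: PhysioSeries,
                 protocol: WorkloadProtocol, subject: Optional[Subject] = None,
                 ma_window: int = DEFAULT_MA_WINDOW, **kw) -> "SubmaximalVO2Model":
        """Build from raw recordings, applying the standard preprocessing."""
        from .preprocessing import preprocess
        return cls(preprocess(hr_raw, ma_window, protocol),
                   preprocess(vo2_raw, ma_window, protocol),
                   protocol, subject, ma_window=ma_window, **kw)

    def _config(self) -> dict:
        return {
            "estimator": self.estimator,
            "embedding_width": self.embedding_width,
            "ma_window": self.ma_window,
            "include_baseline": self.include_baseline,
            "horizon_s": self.horizon_s,
            "refine_bisection": self.refine_bisection,
            "hr_accuracy_bpm": HR_ACCURACY_BPM,
            "extrapolation_step_s": EXTRAPOLATION_STEP_S,
        }

    def fit(self) -> SMOResults:
        # step 1: HRmax target
        if self.hrmax_target is not None:
            hrmax = float(self.hrmax_target)
        else:
            hrmax = whyte_hrmax(self.subject)

        hr = self.hr_series if self.hr_series.phases is not None \
            else self.hr_series.label_phases(self.protocol)
        vo2 = self.vo2_series if self.vo2_series.phases is not None \
            else self.vo2_series.label_phases(self.vo2_protocol)
        if not np.any(hr.phases == "recovery"):
            warnings.warn("record has no recovery phase; fitting warm-up and "
                          "ramp only", stacklevel=2)

        # step 2: HR kinetics fit
        hr_fit = self._fit_one(hr, self.protocol, "hr_fit")

        # step 3: extrapolate HR to the target on the extended ramp
        ramp_mask = hr.phases == "ramp"
        if not np.any(ramp_mask):
            raise PipelineError("extrapolation", "record has no ramp phase")
        t_ramp_end = float(hr.times[ramp_mask][-1])
        x_start = float(hr.values[ramp_mask][-1])
        extended = self.protocol.extend_ramp()
        try:
            hr_ext = extrapolate_to_hrmax(
                hr_fit.params, extended, hrmax, x_start, t_ramp_end,
                horizon_s=self.horizon_s, refine_bisection=self.refine_bisection)
        except ExtrapolationError as e:
            raise PipelineError("extrapolation", str(e)) from e
        # model-data offset diagnostic: model value at the splice point when
        # simulated over the recorded span from the first fitted sample
        fit_span = hr.times[np.isin(hr.phases, ("warmup", "ramp", "recovery"))]
        hr_model_traj = simulate(hr_fit.params, self.protocol,
                                 float(hr.values[hr.times == fit_span[0]][0]),
                                 np.array([fit_span[0], t_ramp_end]))
        splice_offset = float(hr_model_traj.values[-1] - x_start)

        # steps 4-5: VO2 kinetics fit and read-out at t_HRmax_model
        vo2_fit = self._fit_one(vo2, self.vo2_protocol, "vo2_fit")
        vo2_ramp = vo2.phases == "ramp"
        vo2_start = float(vo2.values[vo2_ramp][-1])
        t_vo2_start = float(vo2.times[vo2_ramp][-1])
        t_end = max(hr_ext.t_hrmax_model, t_vo2_start)
        vo2_grid = t_vo2_start + np.arange(0.0, t_end - t_vo2_start + 1.0)
        vo2_ext = simulate(vo2_fit.params, extended, vo2_start, vo2_grid)
        i = int(round(min(hr_ext.t_hrmax_model, vo2_grid[-1]) - t_vo2_start))
        vo2max = float(vo2_ext.values[i])

        return SMOResults(
            hrmax_estimate=hrmax, hr_fit=hr_fit, vo2_fit=vo2_fit,
            t_hrmax_model=hr_ext.t_hrmax_model, vo2max_predicted=vo2max,
            reached=hr_ext.reached, t_ramp_end=t_ramp_end,
            hr_extrapolation=hr_ext, vo2_extrapolation=vo2_ext,
            splice_offset_bpm=splice_offset, config=self._config(),
        )

    def _fit_one(self, series: PhysioSeries, protocol: WorkloadProtocol,
                 stage: str) -> KineticsResults:
        try:
            res = KineticsModel(
                series, protocol, include_baseline=self.include_baseline,
                excitation_smooth_window=self.ma_window,
            ).fit(self.estimator, embedding_width=self.embedding_width)
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        if not res.converged:
            raise PipelineError(stage, f"fit did not converge: {res.message}")
        return res

    def extrapolate_recovery(self, results: SMOResults,
                             recovery_power_W: float = 50.0,
                             duration_s: float = 300.0) -> dict:
        """Extrapolate both variables through a constant-power recovery
        starting at ``t_HRmax_model``; returns {'HR': ..., 'VO2': ...}."""
        if duration_s <= 0:
            return {"HR": SimulatedResponse(np.empty(0), np.empty(0),
                                            results.hr_fit.params),
                    "VO2": SimulatedResponse(np.empty(0), np.empty(0),
                                             results.vo2_fit.params)}
        t0 = results.t_hrmax_model
        grid = t0 + np.arange(0.0, duration_s + 1.0)
        out = {}
        for key, fit, x0 in (
            ("HR", results.hr_fit, results.hr_extrapolation.values[-1]),
            ("VO2", results.vo2_fit, results.vo2max_predicted),
        ):
            prot = WorkloadProtocol(
                segments=(type(self.protocol.segments[0])(
                    start_s=0.0, duration_s=None, kind="recovery",
                    power_start_W=recovery_power_W),),
                name="recovery-extension")
            rel = grid - t0
            sim = simulate(fit.params, prot, float(x0), rel)
            out[key] = SimulatedResponse(grid, sim.values, fit.params,
                                         "recovery-extension")
        return out
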