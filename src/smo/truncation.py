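"""Retrospective termination-point analysis.

To decide how early an incremental test can be stopped without ruining the
VO2max prediction, maximal-test recordings are retrospectively truncated at
the moment HR first reaches 71%, 72%, ..., 95% of the reference HRmax.  The
tail of the true recovery phase is spliced on after the cut — the first
recovery sample whose value has fallen to the level at the cut, time-shifted
to follow it contiguously — so each truncated dataset looks like a genuine
submaximal test with warm-up, shortened ramp and recovery.  The submaximal
prediction pipeline is run on every truncated dataset, its relative error
against the reference VO2max is averaged across subjects per fraction, and
the error-versus-fraction relation is characterised by a linear fit and
correlation.  The recommended termination point (by default the smallest
fraction whose mean error is acceptable) is the study's output; on the
original cohort this compromise was 80% of the estimated HRmax.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import Subject, relative_error, whyte_hrmax
from .pipeline import SubmaximalVO2Model
from .preprocessing import PhysioSeries
from .protocol import WorkloadProtocol

__all__ = [
    "MaximalRecording",
    "TruncationPoint",
    "TruncationStudyResult",
    "truncate_at_fraction",
    "run_truncation_study",
    "recommend_termination",
]

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.71, 0.951, 0.01), 2))
#: Default acceptable mean relative error (%), motivated by the 4–6%
#: intraindividual day-to-day variation of measured VO2max in healthy adults.
DEFAULT_MAX_MEAN_DELTA = 5.0


class NotAttainedError(RuntimeError):
    """The requested HR fraction is never reached during the ramp."""


@dataclass(frozen=True)
class MaximalRecording:
    """One subject's maximal test, preprocessed, with reference maxima."""

    subject: Subject
    hr_series: PhysioSeries  # 1 Hz, smoothed, phase-labelled
    vo2_series: PhysioSeries
    protocol: WorkloadProtocol
    hrmax_measured: float
    vo2max_reference: float


@dataclass(frozen=True)
class TruncationPoint:
    """A truncated-and-spliced dataset for one subject and fraction."""

    fraction: float
    t_cut: float
    hr_series: PhysioSeries
    vo2_series: PhysioSeries
    hr_protocol: WorkloadProtocol
    vo2_protocol: WorkloadProtocol


def _splice(series: PhysioSeries, t_cut: float, match: str) -> PhysioSeries:
    """Prefix up to ``t_cut`` plus the re-timed matching recovery tail."""
    prefix_mask = series.times <= t_cut
    v_cut = float(series.values[prefix_mask][-1])
    rec_mask = series.phases == "recovery"
    rec_vals = series.values[rec_mask]
    if rec_vals.size == 0:
        raise ValueError("recording has no recovery phase to splice")
    if match == "first_below":
        below = np.flatnonzero(rec_vals <= v_cut)
        if below.size == 0:
            warnings.warn("no recovery sample at or below the value at the "
                          "cut; splicing at recovery start", stacklevel=3)
            j = 0
        else:
            j = int(below[0])
    elif match == "nearest":
        j = int(np.argmin(np.abs(rec_vals - v_cut)))
    else:
        raise ValueError(f"unknown match mode {match!r}")
    tail = rec_vals[j:]
    times = np.concatenate([series.times[prefix_mask],
                            t_cut + 1.0 + np.arange(tail.size)])
    values = np.concatenate([series.values[prefix_mask], tail])
    phases = np.concatenate([series.phases[prefix_mask],
                             np.array(["recovery"] * tail.size, dtype=object)])
    return PhysioSeries(times, values, series.variable, phases)


def truncate_at_fraction(hr_series: PhysioSeries, vo2_series: PhysioSeries,
                         protocol: WorkloadProtocol, hrmax_ref: float,
                         fraction: float, match: str = "first_below",
                         ) -> TruncationPoint:
    """Truncate a maximal test where HR reaches ``fraction * hrmax_ref``.

    The cut must fall inside the ramp: a threshold already exceeded during
    warm-up raises, as does one never attained.  Each variable gets its own
    spliced series (the recovery match point differs between HR and VO2) and
    a matching workload schedule whose recovery power is the protocol's.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if hr_series.phases is None or vo2_series.phases is None:
        raise ValueError("series must be phase-labelled")
    threshold = fraction * hrmax_ref
    ramp_mask = hr_series.phases == "ramp"
    pre_ramp = np.isin(hr_series.phases, ("baseline", "warmup"))
    if np.any(hr_series.values[pre_ramp] >= threshold):
        raise NotAttainedError(
            f"{fraction:.0%} of HRmax is reached before the ramp")
    above = ramp_mask & (hr_series.values >= threshold)
    if not np.any(above):
        raise NotAttainedError(
            f"HR never reaches {fraction:.0%} of {hrmax_ref:.0f} bpm in the ramp")
    t_cut = float(hr_series.times[np.argmax(above)])

    hr_spliced = _splice(hr_series, t_cut, match)
    vo2_spliced = _splice(vo2_series, t_cut, match)
    prots = []
    for ser in (hr_spliced, vo2_spliced):
        rec_len = float(ser.times[-1] - t_cut) + 1.0
        prots.append(protocol.truncate_ramp(t_cut + 0.5, rec_len))
    return TruncationPoint(fraction=fraction, t_cut=t_cut,
                           hr_series=hr_spliced, vo2_series=vo2_spliced,
                           hr_protocol=prots[0], vo2_protocol=prots[1])


@dataclass
class TruncationStudyResult:
    """Aggregate error-versus-truncation-fraction analysis."""

    fractions: np.ndarray
    mean_delta: np.ndarray      # % per fraction, across subjects
    sd_delta: np.ndarray
    per_subject: pd.DataFrame   # columns: subject, fraction, delta_pct
    slope: float                # of mean delta (%) on fraction (%HRmax)
    intercept: float
    r_squared: float
    pearson_rho: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    hrmax_source: str
    n_failed: int
    recommended_fraction: float = 0.80

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions,
                             "mean_delta_pct": self.mean_delta,
                             "sd_delta_pct": self.sd_delta})

    def to_dict(self) -> dict:
        return {
            "fractions": [float(f) for f in self.fractions],
            "mean_delta_pct": [float(v) for v in self.mean_delta],
            "sd_delta_pct": [float(v) for v in self.sd_delta],
            "slope_pct_per_pct_hrmax": self.slope,
            "intercept_pct": self.intercept,
            "r_squared": self.r_squared,
            "pearson_rho": self.pearson_rho,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "hrmax_source": self.hrmax_source,
            "n_failed": self.n_failed,
            "recommended_fraction": self.recommended_fraction,
        }

    def plot(self, ax=None):
        """Mean error versus truncation fraction with the linear fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = self.fractions * 100.0
        ax.errorbar(x, self.mean_delta, yerr=self.sd_delta, fmt="o",
                    ms=4, lw=1, capsize=2, label="mean δ ± SD")
        if np.isfinite(self.slope):
            ax.plot(x, self.intercept + self.slope * x, "-",
                    label=f"linear fit (R² = {self.r_squared:.2f})")
        ax.axvline(self.recommended_fraction * 100.0, ls="--", color="gray",
                   label=f"recommended {self.recommended_fraction:.0%}")
        ax.set_xlabel("truncation point (% of HRmax)")
        ax.set_ylabel("mean relative error of predicted VO2max (%)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        lines = [
            "Truncation-point study",
            "=" * 52,
            f"fractions: {self.fractions[0]:.0%} .. {self.fractions[-1]:.0%} "
            f"({self.fractions.size} points), HRmax source: {self.hrmax_source}",
            f"mean delta at {self.fractions[0]:.0%}: {self.mean_delta[0]:.2f}%   "
            f"at {self.fractions[-1]:.0%}: {self.mean_delta[-1]:.2f}%",
            f"linear fit: slope {self.slope:.3f} %/%HRmax, "
            f"intercept {self.intercept:.2f}%, R^2 = {self.r_squared:.3f}",
            f"correlation: rho = {self.pearson_rho:.3f} (p = {self.pearson_p:.2g}); "
            f"Spearman {self.spearman_rho:.3f} (p = {self.spearman_p:.2g})",
            f"recommended termination: {self.recommended_fraction:.0%} of HRmax",
        ]
        if self.n_failed:
            lines.append(f"excluded subject x fraction cells: {self.n_failed}")
        return "\n".join(lines)


def run_truncation_study(recordings: Sequence[MaximalRecording],
                         hrmax_source: str = "measured",
                         fractions: Sequence[float] = DEFAULT_FRACTIONS,
                         match: str = "first_below",
                         max_mean_delta: float = DEFAULT_MAX_MEAN_DELTA,
                         **pipeline_kw) -> TruncationStudyResult:
    """Truncate, refit, extrapolate and score every subject x fraction.

    ``hrmax_source`` selects the extrapolation target: ``'measured'`` uses
    each recording's experimental HRmax (the retrospective design, where
    truncation fractions refer to the same quantity), ``'whyte'`` the
    age/sex estimate (the prospective design).  Per-cell failures are
    logged and excluded rather than fatal.
    """
    if hrmax_source not in ("measured", "whyte"):
        raise ValueError("hrmax_source must be 'measured' or 'whyte'")
    if len(recordings) == 0:
        raise ValueError("no recordings")
    fractions = np.asarray(sorted(float(f) for f in fractions))
    rows = []
    n_failed = 0
    for rec in recordings:
        target = rec.hrmax_measured if hrmax_source == "measured" \
            else whyte_hrmax(rec.subject)
        for frac in fractions:
            try:
                tp = truncate_at_fraction(rec.hr_series, rec.vo2_series,
                                          rec.protocol, rec.hrmax_measured,
                                          float(frac), match=match)
                model = SubmaximalVO2Model(
                    tp.hr_series, tp.vo2_series, tp.hr_protocol,
                    subject=rec.subject, vo2_protocol=tp.vo2_protocol,
                    hrmax_target=target, **pipeline_kw)
                res = model.fit()
                delta = relative_error(rec.vo2max_reference,
                                       res.vo2max_predicted)
                rows.append((rec.subject.id, float(frac), delta))
            except Exception as e:  # per-cell failure: exclude, keep going
                n_failed += 1
                logger.warning("subject %s, fraction %.2f failed: %s",
                               rec.subject.id, frac, e)
    if not rows:
        raise RuntimeError("every subject x fraction cell failed")
    per_subject = pd.DataFrame(rows, columns=["subject", "fraction",
                                              "delta_pct"])
    g = per_subject.groupby("fraction")["delta_pct"]
    mean_delta = g.mean().reindex(fractions).to_numpy()
    sd_delta = g.std(ddof=1).reindex(fractions).to_numpy()

    if fractions.size >= 2:
        x = fractions * 100.0
        lin = stats.linregress(x, mean_delta)
        pear = stats.pearsonr(x, mean_delta)
        spear = stats.spearmanr(x, mean_delta)
        slope, intercept = float(lin.slope), float(lin.intercept)
        r2 = float(lin.rvalue ** 2)
        prho, pp = float(pear.statistic), float(pear.pvalue)
        srho, sp = float(spear.statistic), float(spear.pvalue)
    else:
        slope = intercept = r2 = float("nan")
        prho = pp = srho = sp = float("nan")

    result = TruncationStudyResult(
        fractions=fractions, mean_delta=mean_delta, sd_delta=sd_delta,
        per_subject=per_subject, slope=slope, intercept=intercept,
        r_squared=r2, pearson_rho=prho, pearson_p=pp, spearman_rho=srho,
        spearman_p=sp, hrmax_source=hrmax_source, n_failed=n_failed)
    result.recommended_fraction = recommend_termination(result, max_mean_delta)
    return result


def recommend_termination(result: TruncationStudyResult,
                          max_mean_delta: float = DEFAULT_MAX_MEAN_DELTA,
                          ) -> float:
    """Smallest fraction whose mean error is within ``max_mean_delta`` %.

    Ties break toward the smaller fraction (less exertion).  If no fraction
    qualifies the largest fraction is returned with a warning.
    """
    ok = np.flatnonzero(result.mean_delta <= max_mean_delta)
    if ok.size == 0:
        warnings.warn(
            f"no fraction reaches mean delta <= {max_mean_delta}%; "
            "returning the largest fraction", stacklevel=2)
        return float(result.fractions[-1])
    return float(result.fractions[int(ok[0])])
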