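"""Preprocessing of raw cardiorespiratory recordings.

Breath-by-breath gas exchange and beat-to-beat heart rate arrive on irregular
time grids.  The analysis pipeline consumes series that are (1) linearly
interpolated onto a 1 Hz integer-second grid and (2) smoothed with a centred
15-point moving average.  At the series edges the averaging window shrinks
symmetrically, which keeps the output length equal to the input length and
introduces no phase lag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .protocol import WorkloadProtocol

__all__ = ["PhysioSeries", "resample_1hz", "moving_average", "beats_to_bpm",
           "preprocess"]

DEFAULT_MA_WINDOW = 15


@dataclass(frozen=True)
class PhysioSeries:
    """A sampled physiological time series (HR in bpm or VO2 in L/min).

    ``phases`` optionally labels each sample with the protocol phase
    ('baseline', 'warmup', 'ramp' or 'recovery').
    """

    times: np.ndarray
    values: np.ndarray
    variable: str
    phases: Optional[np.ndarray] = None
    sampling_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.variable not in ("HR", "VO2"):
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.phases is not None:
            ph = np.asarray(self.phases)
            object.__setattr__(self, "phases", ph)
            if ph.shape != t.shape:
                raise ValueError("phases must match times in length")

    def __len__(self) -> int:
        return self.times.size

    def label_phases(self, protocol: WorkloadProtocol) -> "PhysioSeries":
        """Attach per-sample phase labels from a protocol."""
        ph = np.array([protocol.phase_at(t) for t in self.times], dtype=object)
        return replace(self, phases=ph)

    def slice_time(self, t_lo: float, t_hi: float) -> "PhysioSeries":
        """Samples with ``t_lo <= t <= t_hi``."""
        m = (self.times >= t_lo) & (self.times <= t_hi)
        ph = self.phases[m] if self.phases is not None else None
        return replace(self, times=self.times[m], values=self.values[m], phases=ph)

    def value_at(self, t: float) -> float:
        """Linearly interpolated value at time ``t`` (within the span)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside series span")
        return float(np.interp(t, self.times, self.values))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times, self.variable.lower(): self.values}
        if self.phases is not None:
            cols["phase"] = self.phases
        return pd.DataFrame(cols)


def beats_to_bpm(beat_times_s) -> PhysioSeries:
    """Convert beat occurrence times to instantaneous heart rate.

    Each inter-beat interval RR (s) yields one sample 60/RR bpm placed at the
    closing beat time.
    """
    bt = np.asarray(beat_times_s, dtype=float)
    if bt.size < 2:
        raise ValueError("need at least two beats")
    rr = np.diff(bt)
    if np.any(rr <= 0):
        raise ValueError("beat times must be strictly increasing")
    return PhysioSeries(times=bt[1:], values=60.0 / rr, variable="HR")


def resample_1hz(raw: PhysioSeries) -> PhysioSeries:
    """Linear interpolation onto the integer-second grid spanning the record."""
    if len(raw) < 2:
        raise ValueError("resampling needs at least two samples")
    t0 = np.ceil(raw.times[0])
    t1 = np.floor(raw.times[-1])
    if t1 < t0:
        raise ValueError("record shorter than one second")
    grid = np.arange(t0, t1 + 1.0)
    vals = np.interp(grid, raw.times, raw.values)
    return PhysioSeries(times=grid, values=vals, variable=raw.variable,
                        sampling_rate_hz=1.0)


def moving_average(series: PhysioSeries,
                   window_pts: int = DEFAULT_MA_WINDOW) -> PhysioSeries:
    """Centred moving average with symmetric shrinking edge windows.

    The interior uses the full ``window_pts`` window; near the edges the
    half-width is reduced to what fits, so sample ``i`` averages
    ``min(h, i, n-1-i)`` neighbours on each side (``h = window_pts // 2``).
    Output has the same length and time stamps as the input.
    """
    if window_pts < 1 or window_pts % 2 == 0:
        raise ValueError("window_pts must be odd and >= 1")
    if window_pts == 1:
        return replace(series, values=series.values.copy())
    v = series.values
    n = v.size
    h = window_pts // 2
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    for i in range(n):
        hw = min(h, i, n - 1 - i)
        out[i] = (csum[i + hw + 1] - csum[i - hw]) / (2 * hw + 1)
    return replace(series, values=out)


def preprocess(raw: PhysioSeries, window_pts: int = DEFAULT_MA_WINDOW,
               protocol: Optional[WorkloadProtocol] = None) -> PhysioSeries:
    """Standard pipeline preprocessing: 1 Hz resampling then moving average."""
    out = moving_average(resample_1hz(raw), window_pts)
    if protocol is not None:
        out = out.label_phases(protocol)
    return out
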