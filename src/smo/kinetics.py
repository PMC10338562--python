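"""First-order response kinetics of heart rate and oxygen uptake.

Both HR and VO2 during an incremental ergometer test are modelled by the same
first-order differential equation driven by the workload ``P(t)``::

    dX/dt + (X(t) - X0) / tau = (K / tau) * P(t)

``X0`` is the equilibrium value at rest (P = 0), ``K`` the steady-state gain
(response increase per watt) and ``tau`` the time decay: after a step change
in workload the response covers 63.2% (``1 - 1/e``) of its asymptotic change
in a time ``tau``.  For a workload that is constant or linear within a
segment the equation has an exact solution, which :func:`simulate` chains
across the segments and staircase steps of a protocol; the generic numerical
integrator :func:`integrate_numeric` serves as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .protocol import WorkloadProtocol

__all__ = [
    "KineticsParams",
    "SimulatedResponse",
    "closed_form_segment",
    "simulate",
    "integrate_numeric",
]


class ParameterError(ValueError):
    """Raised for physiologically impossible kinetics parameters."""


@dataclass(frozen=True)
class KineticsParams:
    """The parameter triple (K, tau, X0) for one response variable.

    Parameters
    ----------
    K : float
        Gain: steady-state response change per watt (bpm/W for HR,
        L·min⁻¹/W for VO2).
    tau : float
        Time decay in seconds; must be positive.
    X0 : float
        Equilibrium value at zero workload (bpm or L/min); must be positive.
    variable : {'HR', 'VO2'}
    """

    K: float
    tau: float
    X0: float
    variable: str = "HR"

    def __post_init__(self) -> None:
        if not math.isfinite(self.K):
            raise ParameterError("K must be finite")
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ParameterError("tau must be positive")
        if not (math.isfinite(self.X0) and self.X0 > 0):
            raise ParameterError("X0 must be positive")
        if self.variable not in ("HR", "VO2"):
            raise ParameterError(f"unknown variable {self.variable!r}")

    def steady_state(self, power_W: float) -> float:
        """Equilibrium response under constant workload: ``X0 + K * P``."""
        return self.X0 + self.K * power_W


@dataclass(frozen=True)
class SimulatedResponse:
    """A simulated trajectory on a time grid."""

    times: np.ndarray
    values: np.ndarray
    params: KineticsParams
    protocol_name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape:
            raise ValueError("times and values must have the same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


def closed_form_segment(x_init: float, p0: float, ramp_rate: float,
                        params: KineticsParams, dt):
    """Exact solution at elapsed time ``dt`` for ``P(t) = p0 + ramp_rate*t``.

    ``dt`` may be a scalar or an array of non-negative elapsed times measured
    from the segment start, where the response equals ``x_init``.
    """
    K, tau, X0 = params.K, params.tau, params.X0
    dt = np.asarray(dt, dtype=float)
    r = ramp_rate
    forced = X0 + K * (p0 + r * dt) - K * r * tau
    transient = (x_init - X0 - K * p0 + K * r * tau) * np.exp(-dt / tau)
    out = forced + transient
    return float(out) if out.ndim == 0 else out


def _piece_breakpoints(protocol: WorkloadProtocol, t0: float, t1: float) -> np.ndarray:
    """Times in (t0, t1) where P(t) changes slope or jumps."""
    pts = []
    for seg in protocol.segments:
        for b in (seg.start_s, seg.end_s):
            if b is not None and t0 < b < t1:
                pts.append(b)
        if seg.kind == "ramp" and seg.increment_W != 0 and not seg.continuous:
            lo = max(t0, seg.start_s)
            hi = t1 if seg.open_ended else min(t1, seg.end_s)
            if lo < hi:
                k0 = math.ceil((lo - seg.start_s) / seg.step_period_s)
                k1 = math.floor((hi - seg.start_s) / seg.step_period_s)
                for k in range(max(k0, 1), k1 + 1):
                    b = seg.start_s + k * seg.step_period_s
                    if t0 < b < t1:
                        pts.append(b)
    return np.unique(np.asarray(pts, dtype=float))


def simulate(params: KineticsParams, protocol: WorkloadProtocol,
             x_start: Optional[float], t_grid) -> SimulatedResponse:
    """Exact simulation of the response on an arbitrary increasing time grid.

    Workload segments and staircase steps are integrated piece by piece with
    the closed-form solution, so the trajectory is continuous and exact up to
    floating point.  ``x_start`` is the response at ``t_grid[0]``; ``None``
    uses the equilibrium at the initial workload.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        return SimulatedResponse(t_grid, np.empty(0), params, protocol.name)
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    # raises ProtocolError if the grid leaves the protocol span
    protocol.power_at(t0)
    protocol.power_at(t1)
    if x_start is None:
        x_start = params.steady_state(protocol.power_at(t0))

    edges = np.concatenate(([t0], _piece_breakpoints(protocol, t0, t1), [t1]))
    values = np.empty_like(t_grid)
    x = float(x_start)
    for a, b in zip(edges[:-1], edges[1:]):
        seg = protocol.segment_at(a)
        p0 = protocol.power_at(a)
        rate = (seg.increment_W / seg.step_period_s
                if (seg.kind == "ramp" and seg.continuous) else 0.0)
        in_piece = (t_grid >= a) & (t_grid <= b) if b == t1 else \
                   (t_grid >= a) & (t_grid < b)
        if np.any(in_piece):
            values[in_piece] = closed_form_segment(x, p0, rate, params,
                                                   t_grid[in_piece] - a)
        x = closed_form_segment(x, p0, rate, params, b - a)
    return SimulatedResponse(t_grid, values, params, protocol.name)


def integrate_numeric(params: KineticsParams, protocol: WorkloadProtocol,
                      x_start: Optional[float], t_grid,
                      rtol: float = 1e-10, atol: float = 1e-10) -> SimulatedResponse:
    """Adaptive numerical integration of the response ODE.

    Independent of the closed form; used in tests as an oracle and available
    as a fallback for exotic workload shapes.  The maximum step is capped at
    half the staircase period so no workload step is skipped.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        return SimulatedResponse(t_grid, np.empty(0), params, protocol.name)
    t0 = float(t_grid[0])
    if x_start is None:
        x_start = params.steady_state(protocol.power_at(t0))
    if t_grid.size == 1:
        return SimulatedResponse(t_grid, np.array([float(x_start)]), params,
                                 protocol.name)

    def rhs(t, x):
        p = protocol.power_at(min(t, float(t_grid[-1])))
        return (params.X0 - x[0] + params.K * p) / params.tau

    max_step = min(s.step_period_s for s in protocol.segments) / 2.0
    sol = solve_ivp(rhs, (t0, float(t_grid[-1])), [float(x_start)],
                    t_eval=t_grid, rtol=rtol, atol=atol, max_step=max_step,
                    method="RK45")
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return SimulatedResponse(t_grid, sol.y[0], params, protocol.name)
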