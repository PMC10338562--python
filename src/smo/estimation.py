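"""Estimation of the kinetics parameters (K, tau, X0) from recorded data.

Two estimators are provided behind a statsmodels-style model object:

``derivative_regression``
    The response ODE is linear in disguise: rearranged,

        dX/dt = a*X(t) + b*P(t) + c,   a = -1/tau, b = K/tau, c = X0/tau.

    The left side is estimated per sample by local linear regression of the
    response on time over a short centred embedding window, and the
    coefficients (a, b, c) are then obtained by ordinary least squares of the
    estimated derivative on [X, P, 1].  The parameter triple follows as
    tau = -1/a, K = -b/a, X0 = -c/a.

``nls``
    Nonlinear least squares on the trajectory itself: the closed-form
    solution of the ODE (initial condition pinned to the first observed
    value) is fitted to the series over (K, tau, X0).  Used as a cross-check
    and refinement of the derivative estimator.

Both operate on the fit span of the record — warm-up, ramp and recovery.
The resting baseline (P = 0) is excluded by default because pre-exercise
anticipatory heart rate does not follow workload-driven kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
import statsmodels.api as sm

from .kinetics import KineticsParams, ParameterError, simulate
from .preprocessing import PhysioSeries, moving_average
from .protocol import WorkloadProtocol

__all__ = [
    "KineticsModel",
    "KineticsResults",
    "estimate_derivative",
    "fit_derivative_regression",
    "fit_nls",
]

FIT_PHASES = ("warmup", "ramp", "recovery")
DEFAULT_EMBEDDING_WIDTH = 7


class DegenerateDesignError(ValueError):
    """Raised when the regressors are collinear (e.g. constant workload)."""


def estimate_derivative(series: PhysioSeries, embedding_width: int = DEFAULT_EMBEDDING_WIDTH) -> np.ndarray:
    """Per-sample first-derivative estimate by local linear regression.

    A first-order polynomial is fitted to the values over a centred sliding
    window of ``embedding_width`` samples; its slope is the derivative
    estimate at the window centre.  At the series edges the window shrinks
    symmetrically, never below 3 points.
    """
    if embedding_width < 3 or embedding_width % 2 == 0:
        raise ValueError("embedding_width must be odd and >= 3")
    t, v = series.times, series.values
    n = t.size
    if n < 3:
        raise ValueError("series must have at least 3 samples")
    h = min(embedding_width, n if n % 2 == 1 else n - 1) // 2
    out = np.empty(n)

    def _window_slope(idx: int, hw: int) -> float:
        # centred window of half-width hw; at the extremes (hw would be 0)
        # fall back to the nearest 3-point window inside the series
        lo, hi = idx - hw, idx + hw + 1
        if hw < 1:
            lo = min(max(0, idx - 1), n - 3)
            hi = lo + 3
        ts, vs = t[lo:hi], v[lo:hi]
        tc = ts - ts.mean()
        return float((tc @ (vs - vs.mean())) / (tc @ tc))

    uniform = np.allclose(np.diff(t), t[1] - t[0]) if n > 1 else True
    if uniform and n >= 2 * h + 1:
        dt = t[1] - t[0]
        j = np.arange(-h, h + 1, dtype=float)
        w = j / (j @ j) / dt
        out[h:n - h] = np.correlate(v, w, mode="valid")  # correlate does not flip
        for i in range(h):
            out[i] = _window_slope(i, min(i, n - 1 - i))
            out[n - 1 - i] = _window_slope(n - 1 - i, min(i, n - 1 - i))
    else:
        for i in range(n):
            out[i] = _window_slope(i, min(i, n - 1 - i, h))
    return out


def _tent_weights(h: int) -> np.ndarray:
    """Weights phi with slope_estimate = sum_j phi_j * dX/dt(t_{i+j}).

    Derived from the local-linear slope weights c_j = j / sum(j^2) by
    summation by parts and the trapezoid rule; phi sums to 1.  For h = 1
    this gives the classic [1/4, 1/2, 1/4] of the central difference.
    """
    j = np.arange(-h, h + 1, dtype=float)
    c = j / (j @ j)
    # g_m multiplies the increment over [m, m+1], m = -h .. h-1
    g = np.cumsum(c[::-1])[::-1][1:]
    phi = np.zeros(2 * h + 1)
    phi[:-1] += g / 2.0
    phi[1:] += g / 2.0
    return phi


@dataclass
class KineticsResults:
    """Fit results for one response variable.

    Attributes
    ----------
    params : KineticsParams or None
        The estimated (K, tau, X0); ``None`` when the fit did not converge
        to physiologically admissible values.
    bse : dict
        Approximate standard errors for K, tau and X0 (delta method for the
        derivative regression, Jacobian-based for NLS); may be empty.
    r_squared : float
        Coefficient of determination of the underlying regression (the
        derivative regression, or the trajectory fit for NLS).
    residual_sd : float
        Residual standard deviation in signal units (bpm or L·min⁻¹ per
        second for the derivative regression; bpm or L/min for NLS).
    """

    estimator: str
    converged: bool
    params: Optional[KineticsParams]
    raw_coef: dict
    bse: dict
    r_squared: float
    residual_sd: float
    n_points: int
    variable: str
    embedding_width: Optional[int] = None
    message: str = ""

    def to_dict(self) -> dict:
        d = {
            "estimator": self.estimator,
            "converged": self.converged,
            "variable": self.variable,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n_points": self.n_points,
            "embedding_width": self.embedding_width,
            "message": self.message,
        }
        if self.params is not None:
            d["params"] = {"K": self.params.K, "tau": self.params.tau,
                           "X0": self.params.X0}
        d["bse"] = dict(self.bse)
        return d

    def summary(self) -> str:
        lines = [
            f"Kinetics fit ({self.variable}, estimator={self.estimator})",
            "=" * 52,
            f"converged: {self.converged}   n = {self.n_points}   "
            f"R^2 = {self.r_squared:.4f}",
        ]
        if self.params is not None:
            unit = "bpm" if self.variable == "HR" else "L/min"
            rows = [("K", self.params.K, f"{unit}/W"),
                    ("tau", self.params.tau, "s"),
                    ("X0", self.params.X0, unit)]
            for name, val, u in rows:
                se = self.bse.get(name)
                se_s = f" +/- {se:.4g}" if se is not None else ""
                lines.append(f"  {name:>4s} = {val:.5g}{se_s}  [{u}]")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


class KineticsModel:
    """First-order workload-response model bound to one recorded series.

    Parameters
    ----------
    series : PhysioSeries
        Preprocessed (1 Hz) response series; phase labels are taken from the
        series if present, otherwise derived from the protocol.
    protocol : WorkloadProtocol
        The workload schedule of the recording.
    include_baseline : bool
        Include the resting baseline samples in the fit span (default off).
    excitation_smooth_window : int or None
        If the response series was smoothed by a centred moving average,
        pass the same window here so the workload regressor is smoothed
        identically; keeps the linear ODE relation between the smoothed
        signals consistent.
    """

    def __init__(self, series: PhysioSeries, protocol: WorkloadProtocol,
                 include_baseline: bool = False,
                 excitation_smooth_window: Optional[int] = None) -> None:
        self.series = series if series.phases is not None else series.label_phases(protocol)
        self.protocol = protocol
        self.include_baseline = include_baseline
        self.excitation_smooth_window = excitation_smooth_window
        self._fit_mask = self._make_fit_mask()

    def _make_fit_mask(self) -> np.ndarray:
        phases = self.series.phases
        allowed = set(FIT_PHASES) | ({"baseline"} if self.include_baseline else set())
        return np.array([p in allowed for p in phases], dtype=bool)

    @property
    def fit_series(self) -> PhysioSeries:
        m = self._fit_mask
        return PhysioSeries(self.series.times[m], self.series.values[m],
                            self.series.variable, self.series.phases[m])

    def _excitation(self, times: np.ndarray) -> np.ndarray:
        p_full = np.array([self.protocol.power_at(t) for t in self.series.times])
        if self.excitation_smooth_window and self.excitation_smooth_window > 1:
            p_ser = PhysioSeries(self.series.times, np.maximum(p_full, 1e-9), "VO2")
            p_full = moving_average(p_ser, self.excitation_smooth_window).values
        return np.interp(times, self.series.times, p_full)

    def fit(self, method: str = "derivative_regression",
            embedding_width: int = DEFAULT_EMBEDDING_WIDTH,
            init: Optional[KineticsParams] = None) -> KineticsResults:
        if method == "derivative_regression":
            return self._fit_derivative(embedding_width)
        if method == "nls":
            return self._fit_nls(init, embedding_width)
        raise ValueError(f"unknown method {method!r}")

    # -- derivative regression ----------------------------------------

    def _fit_derivative(self, embedding_width: int) -> KineticsResults:
        sub = self.fit_series
        if len(sub) < max(10, embedding_width + 3):
            raise ValueError("fit span too short")
        deriv = estimate_derivative(sub, embedding_width)
        p = self._excitation(sub.times)
        x = sub.values
        if np.ptp(p) < 1e-12 or np.ptp(x) < 1e-12:
            raise DegenerateDesignError("workload and response must vary over the fit span")
        # The local-linear slope at a sample equals, by summation by parts and
        # the trapezoid rule, a tent-weighted average of the true derivative
        # over the embedding window.  Smoothing the regressors X and P with
        # the same tent weights keeps the linear ODE relation between
        # response and regressors consistent (crucial around the workload
        # staircase kinks), so the OLS coefficients are nearly unbiased even
        # though the derivative itself is smoothed.
        h = embedding_width // 2
        phi = _tent_weights(h)
        n = len(sub)
        if n < embedding_width + 4:
            raise ValueError("fit span too short for the embedding window")
        interior = slice(h, n - h)
        x_s = np.correlate(x, phi[::-1], mode="valid")
        p_s = np.correlate(p, phi[::-1], mode="valid")
        deriv = deriv[interior]
        design = sm.add_constant(np.column_stack([x_s, p_s]), has_constant="add")
        ols = sm.OLS(deriv, design).fit()
        c, a, b = ols.params  # const, X coef, P coef
        cov = ols.cov_params()
        converged = a < 0
        params = None
        bse: dict = {}
        msg = ""
        if converged:
            tau, K, X0 = -1.0 / a, -b / a, -c / a
            try:
                params = KineticsParams(K=K, tau=tau, X0=X0, variable=sub.variable)
            except ParameterError as e:
                converged, msg = False, str(e)
            if converged:
                # delta method: g(a,b,c) in the (const, a, b) coef order
                J = np.array([
                    [0.0, b / a**2, -1.0 / a],       # K
                    [0.0, 1.0 / a**2, 0.0],          # tau
                    [-1.0 / a, c / a**2, 0.0],       # X0
                ])
                var = np.diag(J @ np.asarray(cov) @ J.T)
                bse = {k: float(np.sqrt(v)) if v >= 0 else float("nan")
                       for k, v in zip(("K", "tau", "X0"), var)}
        else:
            msg = msg or "non-negative X coefficient: no stable first-order fit"
        return KineticsResults(
            estimator="derivative_regression", converged=converged,
            params=params, raw_coef={"a": float(a), "b": float(b), "c": float(c)},
            bse=bse, r_squared=float(ols.rsquared),
            residual_sd=float(np.sqrt(ols.mse_resid)), n_points=int(deriv.size),
            variable=sub.variable, embedding_width=embedding_width, message=msg,
        )

    # -- nonlinear least squares --------------------------------------

    def _fit_nls(self, init: Optional[KineticsParams],
                 embedding_width: int) -> KineticsResults:
        sub = self.fit_series
        if len(sub) < 10:
            raise ValueError("fit span too short")
        if init is None:
            pre = self._fit_derivative(embedding_width)
            if pre.converged:
                init = pre.params
            else:
                p = self._excitation(sub.times)
                dx, dp = np.ptp(sub.values), max(np.ptp(p), 1.0)
                init = KineticsParams(K=max(dx / dp, 1e-6), tau=40.0,
                                      X0=max(float(sub.values.min()), 1e-3),
                                      variable=sub.variable)
        if init.tau <= 0 or init.X0 <= 0:
            raise ParameterError("initial tau and X0 must be positive")
        x_first = float(sub.values[0])
        t_rel = sub.times

        fit_protocol = self.protocol

        def residuals(theta):
            K, tau, X0 = theta
            pars = KineticsParams(K=K, tau=tau, X0=X0, variable=sub.variable)
            sim = simulate(pars, fit_protocol, x_first, t_rel)
            return sim.values - sub.values

        res = least_squares(
            residuals, x0=[init.K, init.tau, init.X0],
            bounds=([-np.inf, 1e-3, 1e-6], [np.inf, 1e4, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        K, tau, X0 = res.x
        ss_res = float(res.cost * 2)
        ss_tot = float(((sub.values - sub.values.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        dof = max(len(sub) - 3, 1)
        sigma2 = ss_res / dof
        bse = {}
        try:
            JTJ = res.jac.T @ res.jac
            cov = np.linalg.inv(JTJ) * sigma2
            bse = {k: float(np.sqrt(max(v, 0.0)))
                   for k, v in zip(("K", "tau", "X0"), np.diag(cov))}
        except np.linalg.LinAlgError:
            pass
        converged = bool(res.success) and tau > 0 and X0 > 0
        params = None
        msg = "" if res.success else res.message
        if converged:
            try:
                params = KineticsParams(K=K, tau=tau, X0=X0, variable=sub.variable)
            except ParameterError as e:
                converged, msg = False, str(e)
        return KineticsResults(
            estimator="nls", converged=converged, params=params,
            raw_coef={"K": float(K), "tau": float(tau), "X0": float(X0)},
            bse=bse, r_squared=max(min(r2, 1.0), 0.0),
            residual_sd=float(np.sqrt(sigma2)), n_points=len(sub),
            variable=sub.variable, message=msg,
        )


# -- functional wrappers ----------------------------------------------

def fit_derivative_regression(series: PhysioSeries, protocol: WorkloadProtocol,
                              embedding_width: int = DEFAULT_EMBEDDING_WIDTH,
                              **kw) -> KineticsResults:
    """OLS fit of the rearranged ODE via local-linear derivative estimates."""
    return KineticsModel(series, protocol, **kw).fit(
        "derivative_regression", embedding_width=embedding_width)


def fit_nls(series: PhysioSeries, protocol: WorkloadProtocol,
            init: Optional[KineticsParams] = None, **kw) -> KineticsResults:
    """Trajectory-space nonlinear least-squares fit of (K, tau, X0)."""
    return KineticsModel(series, protocol, **kw).fit("nls", init=init)
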