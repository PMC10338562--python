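# Methods

## The response model

Heart rate and oxygen uptake during incremental cycling are modelled as
first-order responses to the ergometer workload P(t):

    dX/dt + (X(t) − X₀)/τ = (K/τ)·P(t)

with three parameters per variable: the resting equilibrium X₀ (bpm or
L/min), the steady-state gain K (bpm/W or L·min⁻¹/W) and the time decay τ
(s). Under constant workload the trajectory relaxes exponentially to
X₀ + K·P; after a workload step it covers 1 − 1/e ≈ 63.2% of its asymptotic
change in a time τ. The model is linear and time-invariant: it has no VO2
slow component, no HR deflection above the second ventilatory threshold and
no cardiovascular drift, which is why it is fitted to *submaximal* spans
where those phenomena are weak.

For workloads that are constant or linear within a segment the equation has
the exact solution

    X(t) = X₀ + K(p₀ + r·t) − K·r·τ + (X(0) − X₀ − K·p₀ + K·r·τ)·e^(−t/τ)

(`closed_form_segment`). Simulation chains this solution across protocol
segments and staircase steps, so trajectories are exact to floating point;
an adaptive Runge–Kutta integrator (`integrate_numeric`, rtol = atol =
1e-10, maximum step of half the staircase period so no workload step is
skipped) is kept as an independent oracle and agrees with the closed form
to better than 1e-6 of the signal range in the test suite.

## Workload protocols

Protocols are ordered, contiguous segments over half-open intervals
[start, start + duration): unloaded baseline, 50 W warm-up, incremental
ramp, 50 W recovery. "25 W/min" is read as a 25-W staircase every 60 s (the
tests are step incremental tests); a continuous linear ramp is available
behind `continuous=True` since the model accommodates either. Two builders
cover the study designs: the retrospective maximal protocol (≤ 6 min seated
baseline, 3 min warm-up, ramp, ≥ 3 min recovery) and the validation
protocol (3 min familiarization, 5 min warm-up, ramp, 5 min recovery).
`extend_ramp` continues the ramp indefinitely with identical increments for
extrapolation, retaining the recovery power (50 W) as metadata.

## Preprocessing

Raw breath-by-breath and beat-to-beat data are linearly interpolated onto
the integer-second grid spanning the record, then smoothed with a centred
15-point moving average. At the edges the window shrinks symmetrically —
this keeps output length and timing unchanged and introduces no phase lag;
a trailing window would delay the HR crossing times used everywhere else.
Beat-to-beat HR is first converted to instantaneous bpm (60/RR at the
closing beat time). No artifact or ectopic-beat correction is attempted.

## Parameter estimation

Rearranged, the model is linear in the observables:

    dX/dt = a·X + b·P + c,  a = −1/τ, b = K/τ, c = X₀/τ.

The headline estimator (`derivative_regression`) estimates dX/dt per sample
as the slope of a local linear regression over a centred embedding window
(default 7 points at 1 Hz — wide enough to suppress noise, narrow relative
to τ ≥ ~20 s dynamics) and regresses it on [X, P, 1] by OLS; the triple
follows as τ = −1/a, K = −b/a, X₀ = −c/a, with delta-method standard
errors. Two consistency details matter numerically:

* The local-linear slope equals (by summation by parts and the trapezoid
  rule) a *tent-weighted* average of the true derivative over the window.
  The regressors X and P are therefore smoothed with the same tent weights
  before the OLS; without this, the smoothing error concentrated at the
  workload staircase kinks correlates with the regressors and can flip the
  sign of `a` even on noise-free data. With it, noise-free recovery is
  within ~1.5% on all three parameters.
* When the series has been moving-average filtered, the workload regressor
  is filtered with the same window (`excitation_smooth_window`); the linear
  ODE relation holds between identically smoothed signals but not between
  a smoothed response and a raw staircase.

A fit is reported `converged=False` (no exception) when a ≥ 0, i.e. no
stable first-order dynamics describe the data.

The cross-check estimator (`nls`) fits (K, τ, X₀) by nonlinear least
squares on the trajectory itself, simulating the closed form with the
initial condition pinned to the first observed value (trust-region
reflective, bounds τ ∈ [1e-3, 1e4] s, X₀ > 0). On noise-free data it is
exact to ~1e-6 relative. When both converge the derivative regression is
reported and NLS kept as a diagnostic.

The fit span is warm-up + ramp + recovery. The resting baseline (P = 0) is
excluded by default: pre-exercise anticipatory HR is not workload-driven
and violates the model. Including it is a flag.

## The prediction pipeline

HRmax is estimated from age and sex (Whyte: 202 − 0.55·age males,
216 − 1.09·age females) unless a measured target is supplied. After fitting
HR, the model is simulated on a 1-s grid from the end of the recorded ramp,
with the ramp extended at identical increments; `t_HRmax_model` is the
first grid time where model HR ≥ target − 0.1 bpm (the 0.1-bpm stopping
accuracy; optional bisection refines within the final second). The
extrapolation restarts from the last smoothed *observed* HR at the ramp
end, not from the model trajectory, so a model-data offset at the splice
point does not bias the crossing time; that offset is reported as a
diagnostic. VO2 is then fitted under the identical workload, simulated
forward from its last observed ramp value, and read at the nearest grid
point to `t_HRmax_model` (grid step 1 s); a horizon cap (default 7200 s)
returns `reached=False` rather than raising. Raising the HRmax target never
decreases `t_HRmax_model` or the predicted VO2max.

The Jurca non-exercise equation, VO2max [ml/kg/min] = 3.5·(18.07 +
2.77·sex − 0.1·age − 0.17·BMI − 0.03·RHR + PAS), serves as the
resting-parameter baseline. PAS is a required numeric input with a
documented category map (0, 0.32, 1.06, 1.76, 3.03 from sedentary to ≥ 3 h
vigorous activity per week); conversion to L/min requires body mass and is
refused without it. Estimator agreement with measured maxima is quantified
by the relative error δ = 100·|measured − predicted|/measured and its
cohort mean.

## Truncation study

Each maximal recording is cut at the first ramp sample where smoothed HR
reaches f·HRmax_ref for f = 0.71 … 0.95. "The corresponding value from the
recovery phase" is read as the first recovery sample whose value has fallen
to or below the value at the cut (forward scan; nearest-value matching is a
flag); the recovery tail from that sample is re-timed to follow the cut
contiguously, separately per variable, and the workload after the cut is
the recovery power. Splices therefore only re-time original samples, never
alter values. The pipeline is run per subject × fraction; mean δ per
fraction is regressed on the fraction (OLS, with R²) and correlated
(product-moment headline, Spearman alongside, since the correlation type is
a free choice). Per-cell failures are logged and excluded, not fatal.

Two HRmax modes exist: `measured` (truncation and extrapolation both refer
to the experimental HRmax — the retrospective design, and the default) and
`whyte` (prospective). The recommended termination is the smallest fraction
whose mean δ is below a threshold defaulting to 5%, the midpoint of the
4–6% day-to-day variation of measured VO2max in healthy adults; ties break
toward the smaller fraction (less exertion), and if nothing qualifies the
largest fraction is returned with a warning.

## Synthetic cohorts

Because no raw recordings are publicly available, validation rests on
synthetic subjects drawn to match the reference cohort's demographics
(male, age ~ N(23.5, 2.0²) y, BMI ~ N(23.9, 3.2²) kg/m², resting HR
uniform 50–70 bpm, PAS at the highest category) with kinetic parameters
from plausible physiological ranges: K_HR 0.3–0.6 bpm/W, τ_HR 25–60 s,
X₀_HR 55–80 bpm; K_VO2 0.009–0.012 L·min⁻¹/W, τ_VO2 25–50 s, X₀_VO2
0.25–0.45 L/min. The true HRmax is the Whyte value plus a N(0, 7²) bpm
subject offset — roughly the residual SD of age-based HRmax equations — so
estimated and true HRmax differ and tests can expose the HRmax
mis-estimation error that a prospective application incurs. The true
VO2max is *defined* as the model VO2 at the moment noise-free HR first
reaches the true HRmax on the maximal protocol, and is re-derivable from
the stored parameters.

Tests are simulated on the protocol, the ramp ending where noise-free HR
reaches the target (true HRmax for maximal tests, 80% of the Whyte
estimate for submaximal ones), followed by 5 min of 50 W recovery.
Measurement noise is iid Gaussian per 1-Hz sample, σ_HR = 2 bpm and
σ_VO2 = 0.08 L/min by default — typical post-averaging magnitudes for
beat-to-beat HR and breath-by-breath VO2. HR and VO2 noise streams are
seeded separately, so a submaximal record is an exact prefix of the
maximal one up to its cut. Passing tests on these cohorts demonstrates the
machinery is unbiased *when the model is true*; it cannot certify accuracy
under slow-component or HR-deflection physiology, which the generator does
not produce.

## Numerical choices and problem sizes

* Extrapolation grid 1 s, stopping accuracy 0.1 bpm, horizon cap 7200 s.
* Derivative-regression embedding width 7 (odd, shrunk at edges, minimum 3
  points); moving-average window 15 points.
* NLS tolerances 1e-12 (xtol/ftol/gtol).
* Degenerate inputs: constant workload or constant response raise a
  degenerate-design error; series shorter than the embedding window are
  rejected; an even smoothing or embedding window is a configuration error.
* The test suite uses fixed seeds throughout; the heaviest checks are a
  17-subject, 25-fraction truncation study (~4 s) and 100 random
  closed-form-versus-integrator comparisons (~20 s), sizes chosen to make
  the statistical assertions stable across seeds while keeping the default
  run fast.

## Known limitations

The model omits the VO2 slow component and HR deflection, so predictions
for subjects with pronounced high-intensity nonlinearity will inherit a
bias no amount of fitting removes. The HRmax equation contributes an
irreducible subject-level error (±7 bpm SD translates to roughly ±2–8% in
predicted VO2max depending on the gains). Treadmill protocols (speed as
the excitation) are out of scope. The published per-subject fit parameters
were never reported, so estimator agreement with the original analysis can
only be validated at the property level, not numerically.
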