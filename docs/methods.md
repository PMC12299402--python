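# Methods

## Model

Untreated tumor volume follows the Gompertz law
V(t) = V(t0)·exp[ln(V∞/V(t0))(1 − e^{−k(t−t0)})]: exponential growth at
initial rate k·ln(V∞/V(t0)) that saturates at the carrying capacity V∞.
The law is phenomenological — any two-parameter sigmoid could play the
same role, and the growth-law interface (`TrajectoryModel`) is pluggable —
but the Gompertz form is the one implemented and tested throughout, as it
describes macroscopic tumor growth well across phenotypes.

Therapy enters as an instantaneous log-volume kill rate F(t) (day⁻¹)
convolved against the growth kernel: ln V(t) gains the term
−∫_{t0}^t F(t′)e^{−k(t−t′)}dt′.  The t→∞ limit of the log-ratio
classifies the outcome: divergence to −∞ is complete response (CR),
a finite negative limit partial response (PR), a non-negative limit no
regression.  For constant F = F0 the limit is ln(V∞/V0) − F0/k; for F
growing linearly in time the integral diverges and the response is
complete.

All model arithmetic is carried out in log-volume space so large
saturation exponents or strongly supercritical therapies never overflow;
volumes are reconstructed by exponentiation only at the interface.

## Fitting

Every fit minimises χ² = Σ((Vᵢ − model(tᵢ))/σᵢ)² with σᵢ = rel_error·Vᵢ
and rel_error = 0.025 by default — the measurement-error level typical of
careful serial caliper or imaging series; a per-file error column
overrides it, and an unweighted option exists for legacy comparisons.
The optimizer is Levenberg–Marquardt (via lmfit) with a multistart grid
(carrying-capacity ratio ∈ {0.2, 1, 5} × k ∈ {0.005, 0.03, 0.1} day⁻¹)
because the objective is flat along the (ln ratio)·k ridge in the
exponential regime; the best optimum is kept, and two runs with the same
configuration serialise bitwise-identically.  1-SD errors come from the
unscaled covariance at the optimum (`scale_covar=False`): σᵢ is an
absolute error model, so parameter SDs propagate rel_error linearly
rather than being rescaled by the reduced χ².

Identifiability: a two-parameter Gompertz fit on early-time data
(k·t_max ≪ 1) cannot separate the carrying capacity from k.  The fit is
declared degenerate when the parameter correlation exceeds 0.999 in
magnitude, any relative SD exceeds 1, or the optimizer cannot produce an
error estimate; the series is then refitted with the single-parameter
exponential model V/V(0) = e^{g t}, g = ln(V∞/V(0))·k, and reported in
PRODUCT mode.  The rate can also be clamped (e.g. to the average in-vivo
value 0.0342 day⁻¹ shipped with the fixtures) to preserve saturation on
very short series.

Two baseline conventions are supported.  Absolute-volume series are
normalised by their first measurement before fitting (the ratio
convention); series that already are ratios — size-reduction
percentages, pre-normalised curves — should be fitted with
`normalize=False` so the exactly-known baseline is not treated as a
noisy datum.  The second convention is what the parameter-recovery and
held-out-prediction simulations use.

SLD series are converted to relative volume by cubing the SLD normalised
to its first value (spherical symmetry); fitting SLD directly is
possible by passing the raw column as `volume`.

## FLASH parameterization

A single (ultra-)high-dose-rate fraction is described by
F(t) = c0 + c1·e^{−c2 t} − cf·t: c0 + c1 is the immediate cell-killing
rate, c2 the decay of the direct effect, and cf the late-time linear
term, plausibly associated with delayed radiation effects or
radiation-triggered immune response.  The kernel convolution has the
closed form implemented in `flash_log_ratio`; the transient term
c1/(k − c2)(e^{−c2 t} − e^{−k t}) has a removable singularity at k = c2,
replaced by its analytic limit c1·t·e^{−k t} when |k − c2| <
10⁻⁹·max(k, c2) (fitted rates can approach this regime).  The early
(k·t ≪ 1) log-slope is k·ln(V∞/V0) − c0 − c1 and the late (k·t ≫ 1)
exponent is linear in t with slope cf/k, so the sign of cf alone decides
between continued regression (cf < 0, CR), a plateau (cf = 0, PR) and
regrowth (cf > 0).  A subcritical trajectory rejoins the untreated trend
at t* = c0/cf + 1/k, where the late exponent equals ln(V∞/V0) exactly;
the model assumes plain Gompertz regrowth beyond t*.

The dose dependence cf(d) = a − b(d − d_ref)^p is stored as data (four
constants), not hard-coded, so other tumor systems can be fitted; the
packaged law (a = 0.000515 day⁻², b = 2.17×10⁻⁷, d_ref = 15 Gy,
p = 3.64) is strictly decreasing above the pivot, and its unique root —
the FLASH critical dose — is found by bracketed Brent root-finding on
[d_ref, d_ref + 2(a/b)^{1/p}].  No conventional-therapy analogue of this
law is provided: the conventional arm is fitted with the same F(t)
machinery but only one dose arm exists in the packaged constants.

## Dose–response and critical doses

Per-dose trajectories are fitted with dose-dependent effective
parameters (FULL mode) or the product g_d (PRODUCT mode).  The dose
dependence of the chosen observable is summarised by
y(d) = baseline − c·d^λ with the baseline anchored at the d = 0 control
fit and held fixed — untreated growth is characterised first, and
therapy effects are measured against it.  c and λ are fitted by bounded
least squares with λ ∈ (0, 30] and a multistart over λ ∈ {0.5, 2, 5, 15}
(the objective is multimodal in the exponent and published fits span
λ = 0.5 to 15; c is optimised on a log scale to keep tiny coefficients
such as 10⁻¹⁷ well-conditioned).  The critical dose solves y(d) = 1 for
the carrying-capacity ratio observable (V_d∞ = V(0), no tolerance band)
or y(d) = 0 for the product observable (sign change), again by bracketed
root-finding; a baseline already at or below threshold reports 0 as a
boundary value, and c = 0 reports no critical dose.

When only per-dose log-size slopes are available (a drug dose changed
mid-treatment), `interpolate_critical_dose` places the critical dose at
the zero crossing of the straight line through (dose, slope) pairs.

## Fractionation

Between doses the volume follows one Gompertz step minus the
per-fraction log-reduction RT(n); the inversion
RT(n) = ln(V(n⁻)/V(n+1⁻)) + ln(V∞/V(n⁻))(1 − e^{−kΔt}) is exact by
construction.  The inter-dose ratio factorises as RG·TH with
RG = exp[ln(V∞/V(n⁻))(1 − e^{−kΔt})] ≥ 1 below saturation and
TH = e^{−RT}.  TH is defined with the negative exponent so that
RG·TH = V(n+1⁻)/V(n⁻) holds identically and therapy factors below one
mean net cell killing — the convention consistent with the stepping
exponent and with the packaged patient decomposition table.

The cumulative effect RTtot(n) = Σ RT(m)e^{−kΔt(n−(m+1))} and the strict
regression condition ln(V∞/V(1⁻))(1 − e^{−(n−1)kΔt}) < RTtot(n) are
implemented for fixed Δt and generalised to irregular schedules by
replacing the discounts with e^{−k(t_n − t_m)}; the general form reduces
exactly to the fixed-interval one.  The next-dose decision extrapolates
the RT series by ordinary least squares on the dose index (the minimal
"continue the trend" assumption; last-value carry-forward is available)
and evaluates the same discounted condition including the extrapolated
term — with three observed values, the four-term sum against
1 − e^{−4kΔt}.  Post-dose volumes V(n⁺), when recorded, are parsed but
enter no computation.

## Prediction and classification

Above the critical dose the monitored series is fitted directly with
effective parameters; the forward curve from the end of therapy (te, the
last fitted observation) is the Gompertz law anchored at V(te).  The CC
ratio V∞ᵉᶠᶠ/V(te) classifies the outcome with configurable thresholds:
CR-like below 0.1, regrowth-risk above 2.0, PR-like between.  The
published language for these regimes is qualitative ("very small",
"close to", "much larger"); 0.1 and 2.0 are the package's documented
defaults, not fitted quantities.  Extrapolation requires kᵉᶠᶠ > 0 and is
refused otherwise — a non-positive effective rate is outside the
saturating forward-law regime.

`truncated_fit_predict` fits only observations up to a cutoff, reports
percent residuals at each held-out time and the χ²/dof of the full
series under the truncated-fit parameters, and attaches the
classification.  With the cutoff beyond the last point it reproduces the
full fit bitwise.

## Synthetic data

Generators sample the untreated law, the single-dose closed form, or a
fractionated schedule with planted RT values (or a kill-rate function,
in which case the implied per-interval RT ground truth is returned from
the kernel integral).  Noise is multiplicative Gaussian with relative SD
0.025 by default, matching the χ² weighting, truncated at −3 SD so
volumes stay positive (the truncation biases the mean by ~0.004·SD,
negligible against the 3-standard-error bands the tests use).  All
generators are deterministic under a fixed seed.

What the generators emulate: serial size measurements with
state-independent relative error on an exact model curve.  What they do
not: irregular real-world sampling gaps, measurement-modality switches
(caliper vs MRI), inter-lesion aggregation in SLD, or model
misspecification of the growth law itself.  Passing recovery tests
therefore demonstrate the estimator chain is correct and calibrated
under the stated error model, not that the Gompertz form is adequate for
any particular tumor.

## Numerical choices

* Kernel quadrature: adaptive (QUADPACK) with absolute tolerance 1e−10,
  relative 1e−8; closed forms exist for constant and FLASH kill rates,
  so the tolerance is verified rather than assumed.
* CR detection: log-ratio below −20 and still decreasing at the horizon
  (e^{−20} is below any measurable volume fraction); convergence of the
  tail within 1e−3 relative declares a finite limit; oscillatory,
  non-converged tails return an indeterminate flag rather than a hard
  error.
* Optimizer tolerances xtol = ftol = 1e−12; λ-law fit bounded in
  log-c ∈ [−80, 20].
* dof = 0 fits (exact interpolation) are allowed; χ²/dof is reported as
  None.
* Ties in the regression condition are resolved as "no regression"
  (strict inequality).

## Problem sizes

Simulation-based tests use 8–10 point series, 2.5% noise, 60–200
replicates, and dose designs of 4 levels; the structural equivalence
checks run 100–200 random parameter draws.  These sizes make the whole
suite run in seconds while keeping Monte-Carlo rates (coverage ≥ 90%,
held-out residual fractions) statistically stable.

## Known limitations

* No mechanistic dose→F(t) mapping: dose enters only through fitted
  effective parameters or estimated RT values.
* No spatial heterogeneity, no alternative sigmoids beyond the pluggable
  interface, no Bayesian posteriors or bootstrap intervals (χ² SDs
  only).
* The cell-line dose-law fixture for line 36 round-trips to a critical
  dose of ≈7.3 Gy from its published constants versus the published
  7.1 Gy — consistent with rounding of the published c and λ; the value
  is carried as a fixture with a tolerance note.
* Classification thresholds and the RT extrapolation rule are
  documented conventions, configurable by the caller.
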