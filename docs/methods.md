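# Methods

## Data model

The package operates on grouped person-year tables: each cell is a
stratum (city × sex × age-at-exposure category × attained-age category
× calendar-period category × dose category) carrying person-year-
weighted mean attained age *a* (years), mean age at exposure *e*
(years), mean weighted colon dose *D* (Gy; the neutron component is
assumed weighted upstream), person-years at risk and integer death
counts per cause. All hazard evaluation uses the cell means; category
indices are opaque labels. The canonical file format is CSV with fixed
column names (`city, sex, agexcat, agecat, periodcat, dosecat,
mean_age, mean_agex, mean_dose_gy, pyr, deaths_<cause>`), chosen
because the historical fixed-width cohort files are restricted and
undocumented; column names are overridable.

Stratified summaries assign cells to (dose × attained-age) groups by
half-open intervals [lo, hi) on the cell means. Printed stratified
tables in this literature often use right-closed intervals
("0.1 < D ≤ 0.5"); the convention is therefore a switch
(`right_closed=True`), not a guess.

## Hazard model

Total hazard per cell, in deaths per person-year:

* ERR transfer: h = h₀ · (1 + err(D) · ε(s, a, e))
* EAR transfer: h = h₀ + ear(D) · ε(s, a, e)

with risk read off as ERR = h/h₀ − 1 and EAR = h − h₀. An ERR-transfer
model therefore implies a city/sex-dependent EAR (EAR = h₀·ERR) and
vice versa; `group_conversion_factor` converts risk quoted for one
city/sex group to another via the person-year-weighted baseline-hazard
ratio.

### Baseline

log h₀ = intercept + city·1[Nagasaki] + sex·1[female]
         + log_age·ln(a/70) + Σ_k s_k·max(0, ln a − ln t_k)
         + γ_e·(e−30)/10 + Σ_j s'_j·max(0, e − u_j)/10

The truncated-basis construction guarantees continuity of the
log-hazard at every knot and h₀ > 0 everywhere. Any coefficient can be
excluded (structural zero), fixed, or free. Free knot *positions* enter
the optimizer through a logistic map squashed between the neighbouring
fixed knots (or the domain bounds, 18–110 y for attained age), so knot
ordering cannot be violated during a fit; adjacent free knots sharing a
window are sorted after the transform, which is a pure relabelling of
an order-symmetric parameterization. Reference covariates are
Hiroshima male, a = 70 y, e = 30 y.

### Dose–response shapes

Eleven candidate shapes (ids 1–11): linear (LNT), quadratic,
linear-quadratic, linear-exponential, linear threshold, tanh-smoothed
step, step-with-slope, step-with-slope-offset, two hormesis-like shapes
and a 3-step categorical shape. Conventions worth noting:

* The dose-squared coefficient in shapes 2–3 is multiplied by the
  dosimetry-error adjustment 1.12 (1.15 available as the revised
  alternative); the constant is a structural configuration, not a fit
  parameter.
* The step (shape 6) is implemented as
  0.5·scale·[tanh(tanh_slope·(D − D_th)) + 1] so the threshold can be
  estimated rather than assumed; tanh_slope defaults to 10⁵ per Gy,
  at which the function differs from a hard step by < 10⁻⁶ everywhere
  more than 1 mGy from D_th. The slope is treated as a fixed structural
  constant by default (it may be freed explicitly). The symbol
  `tanh_slope` avoids the collision between "s" as sex and "s" as the
  step slope.
* Both hormesis-like shapes return exactly zero below a fixed 5 mGy
  floor.
* The linear-exponential shape (4) evaluates to err1 at zero dose by
  its formula; it passes through the origin only when err1 = 0.
* The categorical shape (11) is applied without dose-effect modifiers
  by default (whether the original analyses modified it is not
  documented); its default boundaries are configurable per endpoint.

### Dose-effect modifiers

ε(s, a, e) = exp(θ_s·1[female]) · (a/70)^η · exp(γ·(e−30)/10), each
term individually includable — the standard LSS centring. With all
terms excluded ε ≡ 1; ε > 0 always. The exact functional form used in
the original analyses is not published in full, so this documented
default is configurable by construction (terms are independent and
each can be dropped).

## Fitting

Objective: grouped Poisson deviance
dev = 2 Σᵢ [dᵢ ln(dᵢ/λᵢ) − (dᵢ − λᵢ)], λᵢ = h(cellᵢ)·PYᵢ, with the
d ln(d/λ) term zero for empty cells (standard saturated-model limit).
Points where the hazard is nonpositive (possible under ERR transfer
with strongly negative excess, or EAR with a large negative term)
return a large penalty (10¹⁰), keeping the optimizer inside the
admissible set.

Optimizer contract: quasi-Newton (BFGS with numerical gradients) from
each start, followed by a Nelder-Mead polish that is robust to the
kinks of the threshold shapes; the better optimum wins. Three
additional perturbed restarts (10% relative, deterministic in the
`seed` option) guard against local minima; the best optimum across
restarts is kept. Convergence tolerance 10⁻⁶ on the deviance, at most
10⁴ evaluations per stage. The hybrid was adopted after observing that
a pure simplex stalls in the curved valley created by a free knot
position, while a pure quasi-Newton method can step across a threshold
kink.

Wald covariance: 2 × inverse of the deviance Hessian at the optimum
(observed information), Hessian by central finite differences with step
10⁻⁴·max(|θ|, 1). A singular or indefinite Hessian flags the covariance
unavailable (NaN standard errors) rather than failing the fit.

### Threshold profiling

Shapes carrying D_th are profiled over a fixed grid (default: 0.0001–
0.0005 Gy by 0.0001, 0.001, 0.005, 0.01–0.09 by 0.01, 0.1–0.9 by 0.1,
1 and 2 Gy — 27 values); all other parameters are refit at each grid
value and the smallest deviance wins, ties breaking toward the lowest
dose. For the linear-threshold shape the best grid point can seed a
final fit with D_th free (the kink makes the profile deviance locally
smooth between observed doses).

A caveat the package states rather than hides: the Wald curvature of a
kinked threshold parameter reflects only the smooth piece of the
deviance between adjacent observed doses and badly understates the real
uncertainty of D_th. Threshold uncertainty should be judged from the
deviance profile over the grid; correspondingly, grid-selected
thresholds are held fixed during Latin-hypercube sampling (their grid
uncertainty is not propagated), and the recovery test battery checks
Wald intervals for the smooth parameters while checking the threshold
against the grid.

### Likelihood-ratio testing and streamlining

For nested models the deviance difference is χ²-distributed with the
number of extra parameters as degrees of freedom. The decision
threshold is quoted at the two decimals conventional in this field
(3.84 for 1 df at the 5% level, 5.99 for 2 df), with the boundary
counted as an improvement ("at least 3.84").

Baseline streamlining is iterated backward elimination: every free
baseline coefficient (scalar terms and knot slope changes; the
intercept is protected by default) is tested by fixing it at zero and
refitting everything else; the least significant candidate is removed
if its removal costs less than the critical value, and sweeps repeat to
a fixed point. Whether the original procedure iterated or made a single
pass is not documented; iteration is the default here because it is the
fixed-point completion of the described test, and the audit trail
(every test's parameter, Δdev and decision) makes either variant
reproducible. After elimination, candidate knot positions are freed one
at a time and kept only if they buy the critical value per added
parameter. Refits start warm from the current best estimates.

## Model selection and MMI

AIC = dev + 2 N_par, with free knots counted as parameters. Akaike
weights follow the exp(−ΔAIC/2) formula, computed on ΔAIC so the result
is shift-invariant, and sum to one within 10⁻¹².

One documented discrepancy: in the published cardiovascular selection
table, the weight column pairs 0.1918 with the quadratic model
(ΔAIC = 0.32) and 0.3084 with the step model (ΔAIC = 1.93), whereas
direct evaluation of the weight formula on those ΔAIC values gives the
reverse pairing (0.3084 for ΔAIC = 0.32, 0.1918 for ΔAIC = 1.93). The
implementation follows the formula; the printed column ordering appears
transposed.

MMI sample allocation multiplies the weights by the total sample size
(default 10⁴) and rounds by largest remainder so the counts sum
exactly. Per-model risk distributions come from Latin-hypercube
sampling of the fitted parameters: each coordinate's standard normal is
stratified so its marginal hits each of n equiprobable bins exactly
once, and correlations are induced by a linear transform L (LLᵀ = Wald
covariance, computed by eigendecomposition with negative eigenvalues
clipped at zero and logged). Sampled parameter vectors are pushed
through the hazard in one vectorised evaluation; draws that make the
hazard nonpositive are regenerated from the unstratified normal (count
logged), and more than 10% inadmissible draws aborts with an error
signalling an unstable fit. Pooled summaries use empirical percentiles
with linear interpolation; the "90% CI" is the [5th, 95th] percentile
interval of the pooled realizations.

`mmi_dose_response` additionally exposes the weight-averaged point
dose–response Σ p_m err_m(D) (valid within one transfer type), which
can be scored as a fixed dose–response inside the Poisson deviance.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:
strata over 2 cities × 2 sexes × 5 age-at-exposure bands × 5
attained-age bands × 2 periods × dose categories, restricted to
feasible strata where attained age exceeds age at exposure by at least
23 years (follow-up two decades after exposure). Person-years are
allocated deterministically by the product of marginal weights,
totalling 1.2 × 10⁶ by default; dose-category means default to
{0.0025, 0.03, 0.2, 0.75, 1.5, 2.5} Gy with person-year weights
{0.55, 0.25, 0.12, 0.05, 0.02, 0.01}, reproducing the low-dose
concentration that MMI behaviour depends on. Cell means receive small
jitter (±1 y on ages, ±5% on doses) emulating the variation of
person-year-weighted means in real grouped data. Death counts are
Poisson with mean h_true·PY. The default truth is an ERR-LNT model
(err = 0.2 per Gy) over a baseline rising as (a/70)⁵ with a female
log-offset of −0.3, its intercept calibrated deterministically so
expected deaths per endpoint are 4,000 — the order of magnitude of the
emulated cohort. Randomness is split into per-purpose substreams
(age jitter, dose jitter, deaths) of one seed, so toggling one source
does not shift another; a fixed configuration is byte-identical across
runs.

What the generator does **not** emulate: individual-level survival and
censoring, dosimetry measurement error (assumed corrected upstream),
healthy-survivor selection dynamics (handled in real analyses by cohort
restriction), cause-of-death misclassification, and any correlation
between causes (multiple causes are drawn independently with the same
true hazard). Passing tests therefore demonstrate correctness of the
inference machinery under the stated Poisson model, not robustness to
these real-data complications.

Threshold-recovery experiments use a denser dose-category layout
(means 0.0025–2.0 Gy with extra categories at 0.45/0.55/0.65/0.85) than
the 6-category default: a threshold dose is only identified up to the
gap between adjacent observed mean doses, and the default layout leaves
0.24–0.6 Gy empty. The dense layout also keeps each category's ±5%
jitter strictly inside one 0.1-Gy profiling interval, so grid values
never split a category. Real person-year files carry ~20 dose
categories, making this the realistic condition for threshold work.

## Problem sizes and tolerances used in validation

The validation suite runs the default cohort scale (912 cells,
1.2 × 10⁶ person-years, ~4,000 deaths). Recovery batteries use 20
replicates per shape (3-Wald-SE criterion, ≥ 95% pass), interval
coverage uses 200 replicates of 10⁴-realization LHS distributions
(target 90% ± 5%), and the null calibration of the 1-df LRT uses 500
replicates (tolerance three binomial standard errors around 5%). These
sizes were chosen so Monte-Carlo error is small relative to each
tolerance while the whole suite remains a routine local run. The
acceptance script uses 100 coverage and 200 null replicates for the
same diagnostics.

## Known limitations

* Wald-based uncertainty (and hence LHS propagation) assumes local
  quadratic log-likelihood; it is unreliable for threshold positions
  (see above) and can understate uncertainty for weakly identified
  step heights at doses with few deaths.
* The baseline family is a configurable log-linear spline; it
  reproduces the qualitative structure of published LSS baselines
  (age knots, city/sex terms, age-at-exposure dependences) but not any
  specific published coefficient set, so absolute deviances are not
  comparable to analyses of the restricted cohort file.
* Backward elimination order (least significant first, one per sweep)
  is a documented choice; different orders can reach different reduced
  models when candidates are correlated. The audit trail records every
  decision so alternatives can be replayed.
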