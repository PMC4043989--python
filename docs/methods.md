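# Methods

## The occurrence model

The acoustic datum is a station-month count: `k_hours` of `n_hours`
analyzed hours contained at least one song call of one type. Because a
singing whale is typically audible for consecutive hours, the hourly
presence indicators are positively correlated and the monthly counts are
over-dispersed relative to a binomial. We model them as beta-binomial with
mean `mu` (the probability of hearing at least one call in an hour) and
over-dispersion `sigma`, parameterized through the beta mixing density
`Beta(mu/sigma, (1-mu)/sigma)`. In this parameterization the count
variance is `n*mu*(1-mu)*(1 + sigma*(n-1)/(1+sigma))`, which collapses to
the binomial variance as `sigma -> 0`; `sigma` therefore acts as a pure
variance-inflation parameter with an interpretable limit. The exact
parameterization and link pair are a design choice of this package; any
parameterization with the same binomial limit fits the same data almost
equivalently, but coefficient values are not transferable across
parameterizations.

Both parameters carry additive predictors, in the manner of
distributional regression (GAMLSS): logit link on `mu`, log link on
`sigma` (log guarantees positivity; "canonical" is not meaningful for a
dispersion parameter). Predictors are longitude, latitude and month only —
the covariates that also exist for historical catches. Month is a
12-level factor (January reference); time is binned to months because
sub-monthly resolution is not supported by the lag between presence and
singing, and longer bins would blur migration.

### Spline basis

Spatial smoothers are unpenalized natural cubic regression splines with
4 degrees of freedom per covariate: 5 knots at equally spaced quantiles,
cardinal basis (the j-th basis function interpolates the j-th standard
basis vector at the knots), first column dropped for identifiability
against the intercept. Natural splines are linear beyond the boundary
knots, so predictions away from the hydrophone network extrapolate
linearly on the link scale rather than cubically; predictions outside the
knot box are flagged (`return_extrapolation=True`). The fixed df = 4 makes
the six candidate structures use exactly 40, 34, 21, 28, 20 and 14
coefficients. The basis is serialized by its knots alone, so fits
round-trip through JSON.

Longitude is handled in degrees east [0, 360) so the basin is contiguous
across the dateline; files may use signed degrees and are normalized on
read. Files are written in degrees east, which keeps write-then-read
round trips bit-exact (converting back to signed degrees is lossy in
floating point).

### Fitting and the convergence flag

The joint coefficient vector is estimated by maximum likelihood with
analytic gradients: multi-start L-BFGS-B (empirical-logit start for the
`mu` intercept, `sigma = 0.1`, plus jittered starts), followed by damped
Newton polishing with the analytic Hessian (digamma/trigamma terms).
Quasi-Newton alone stalls when objective decrements reach machine
precision, which for large-count data happens while the gradient is still
well above any fixed small tolerance; the Newton polish closes that gap.

A fit is declared converged when either the per-observation mean gradient
has infinity norm below 1e-5, or a full damped-Newton step improves the
negative log-likelihood by less than 1e-6 nats — i.e. the log-likelihood
is determined to far below the resolution at which AICc comparisons
operate. A gradient-only criterion is not scale-invariant (the same model
on more hours of data has a larger gradient at the same relative
accuracy), so the Newton-decrement form is the primary criterion. Fits
pushed to the boundary (all fitted `mu` below 1e-4 or above 1 - 1e-4, as
happens on all-zero resamples) are flagged non-converged rather than
trusted. Failure never raises: the flag propagates so that ensemble
iterations with failed refits can be discarded, mirroring the few-percent
refit failure rates this bootstrap is known to produce.

The observed information from the final Hessian provides coefficient
standard errors (`bse`) on the link scales.

### Model selection

Candidates are ranked by AICc, `-2 loglik + 2 df + 2 df (df+1)/(n-df-1)`,
with `n` the number of station-month rows. Non-converged candidates sort
last and are excluded from the reference minimum. Maximum-likelihood
nesting (a richer structure never fits worse) is enforced by test.

## The prediction model and the ensemble

The per-catch probability of eastern membership is
`p_E / (p_E + lambda * p_W)`. `lambda` absorbs everything that makes the
call-probability ratio differ from the density ratio: relative calling
rates, behavioural differences, differential depletion. Base case
`lambda = 1`; the sensitivity analysis draws `lambda` log-uniformly on
(0.5, 2) — a fourfold range, equally likely low or high on the log scale —
one draw per iteration, shared by all catches in that iteration. `lambda`
multiplies `p_W`, so larger values shrink eastern assignments; totals are
non-increasing in `lambda` by construction, and swapping the two fits
while inverting `lambda` complements every probability exactly.

One ensemble iteration: draw a catch realization; if the bootstrap is on,
resample the acoustic rows of each call type with replacement and refit
both models (whole iteration discarded and redrawn — fresh realization
included — if either refit fails); draw `lambda`; split; aggregate by
year. The run records attempts and failure counts and aborts if more than
half of a rolling 100-attempt window fails. Bootstrap refits warm-start
from the base-fit coefficients with a single optimizer start; base fits
use three starts.

Assignment is `expected` by default (per-year sums of probabilities),
which minimizes Monte Carlo noise; `bernoulli` draws hard labels. Both
conserve the conflated count per year exactly. Percentiles use linear
interpolation between order statistics; report tables round to integers
only at serialization. The totals row of a percentile table is the
percentile of per-iteration totals, not the sum of per-year percentiles.

The uncertainty decomposition expresses each nested ensemble's 95%
interval width (catch-only; catch + bootstrap; catch + bootstrap +
`lambda`) as a rounded percentage of the full width; the last entry is
100 by construction.

## Catch imputation

Five location-uncertainty categories, most certain last:

- `certain` and `inferred`: coordinates used as is. The averaging that
  produces an inferred position from neighbouring same-day catches is a
  data-preparation step (`infer_from_neighbours`), after which the record
  carries fixed coordinates.
- `soviet`: uniform draw inside the record's log-derived rectangle.
- `iwc_region`: draw with replacement from donor positions (reported blue,
  fin, sei and common minke whale catches) in the same management region —
  this imports the spatial pattern of real whaling effort instead of
  spreading catches uniformly over mostly empty rectangles.
- `partial`: month first (kept if known, else drawn), then a draw from
  same-expedition-year donor positions in that month; if that month has no
  donors the pool widens to all months with a warning.

Missing months are drawn from the donor month distribution restricted to
the expedition's operating period (all months if unknown), renormalized;
with no donors in the allowed months the draw is uniform over them.
Donor pools are multisets — duplicates count. Known fields are never
modified. The unspecified-species allocation applies, in order: the fixed
16.4% share for flagged early coastal-Japan rows; the same-year blue
proportion where species-identified catches coexist; otherwise the blue
proportion of adjacent years, widening ±1, ±2, ±3 before giving up with a
warning and zero. Counts round to nearest integer, ties to even.

## Length validation

Mature females (recorded maturity, or a 21 m length proxy when maturity
is unrecorded — the threshold is configurable because the underlying
maturity criterion is external to this package) are grouped per iteration
by predicted probability above/below 0.5. A Welch two-sample t-test
compares lengths (reported as west minus east, positive when western
whales are longer); probability is regressed on length by OLS, the slope
sign being the criterion. Iterations with an empty group or zero length
variance are flagged undefined and excluded from summaries with a
warning. Label swapping negates the difference and flips the slope sign
exactly.

## The synthetic world

The generator emulates the structure of the real study system: two smooth
occurrence surfaces (logistic-quadratic in scaled lon/lat plus 12 additive
month offsets — no interaction terms, so the truth lies inside the
additive model class and recovery is well-posed), a dispersion field
(log-quadratic with month offsets and an optional hard floor), a
hydrophone network of ~32 stations with contiguous activity windows of
6–12 months at 720 analyzed hours per month, catches placed by an effort
surface (sum of the two densities plus a northern coastal bump) across
1905–1971 with two intensity eras, true population labels drawn Bernoulli
from the density ratio, the five uncertainty categories at proportions
41/9/5/2/43 with month-missingness matched per category, donor pools
guaranteed to contain each constrained catch's true location, and normal
lengths (eastern mean 22.0 m, western 22.91 m, sd 1 m).

Defaults are deliberately "hotspot-like": basin-average call probability
around 0.1–0.2 with seasonal peaks near 0.5, and constant over-dispersion
sigma = 0.4. What the generator does *not* emulate: spatial
autocorrelation between stations, year effects in the surfaces,
oceanographic drivers of occurrence, non-stationary whaling selectivity.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the stated assumptions, not robustness to their
violation on real data.

### Simulation-study conditions

- *Model selection* (`selection_study`): dispersion must be strongly
  non-constant for the data to discriminate all six structures, as a
  single count per station-month carries little dispersion information.
  The study world uses sigma between ~0.3 (hard floor) and ~8, with both
  spatial curvature and seasonal offsets, on 100-station networks; the
  full additive/additive structure then wins the AICc ranking in
  essentially all seeds, and the binomial candidates lose by enormous
  margins.
- *Surface recovery* (`recovery_study`): smooth default-shape world at the
  reference dispersion sigma = 0.3, ~200 station-months, error measured as
  mean |mu_hat - mu_true| over a 20 x 20 grid spanning the station
  bounding box (accuracy outside the sampled region is an extrapolation
  question, not a recovery question), averaged over months and five seeds,
  with the structure chosen by AICc per dataset.
- *Coverage* (`coverage_study`): 20 default worlds of 800 catches, 200
  iterations each with bootstrap refits and Bernoulli assignment — the
  interval is predictive of the *realized* eastern count, which is the
  natural target when truth is a finite set of labels.
- *Interval ordering and monotonicity*: one world, the three nested
  ensembles at 200 iterations; monotonicity in `lambda` is checked on a
  fixed realization with fixed fits, where it holds deterministically.
- *Validation power* (`validation_power_study`): 200 replicates of 129 +
  129 mature females at the 0.91 m contrast, sd 1 m.

Study sizes (50 selection seeds, 5 recovery seeds, 20 worlds x 200
iterations) are the package's choice of a desk-scale design with stable
pass/fail behaviour.

## Degenerate inputs and numerical details

- `k > n`, months outside 1–12, mixed call types, empty tables: rejected
  with specific errors.
- Spline construction requires at least df + 1 distinct covariate values;
  the error names the covariate. Bootstrap resamples violating this come
  back as non-converged fits, not exceptions.
- Linear predictors are clipped at ±30 (logit) / ±25 (log) inside the
  likelihood for numerical safety.
- `p_E` where both fitted call probabilities underflow to zero returns
  0.5 with a warning — the data say nothing there.
- Months absent from training data predict at the reference-month level
  with a warning.
- All randomness flows from explicit integer seeds; identical seeds give
  byte-identical outputs, including CSVs.

## Known limitations

Unpenalized splines can run away at sparsely sampled boundaries of the
network (the linear link-scale extrapolation bounds but does not remove
this); there is no spatial correlation model between stations; `lambda`
is global, with no spatial or temporal structure; the maturity proxy is a
stand-in for the external length-at-maturity criterion; and the
convergence flag is a numerical-stalling diagnostic, not a guarantee of a
global optimum.
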