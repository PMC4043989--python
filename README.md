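# callsplit

Separating conflated whale catch records between two populations using
acoustic call patterns.

Two blue whale (*Balaenoptera musculus*) populations share the North
Pacific — an eastern (ENP) and a western (WNP) population — and each sings
a distinct, stereotyped song call. Commercial whaling (1905–1971) recorded
catches only as "blue whales", so the historical catch series conflates
the two populations, which blocks any assessment of their depletion and
recovery. `callsplit` implements a two-stage acoustic method for splitting
such a conflated series, together with a synthetic-data generator that
makes every stage testable against known truth.

## The method

**Stage 1 — occurrence models.** Hydrophone data arrive as station-month
records: $k$ hours with at least one song call of a type out of $n$
analyzed hours. Consecutive hours are serially dependent (a singing whale
is heard for many hours in a row), so counts are over-dispersed relative
to a binomial. Each call type gets a beta-binomial additive model in the
GAMLSS (distributional regression) style, with additive predictors on
*both* parameters:

$$k \sim \mathrm{BetaBinomial}(n,\; a = \mu/\sigma,\; b = (1-\mu)/\sigma)$$

$$\mathrm{logit}(\mu) = \beta_0 + s(\mathrm{lon}) + s(\mathrm{lat}) + \mathrm{month},\qquad
\log(\sigma) = \gamma_0 + s(\mathrm{lon}) + s(\mathrm{lat}) + \mathrm{month},$$

where $s(\cdot)$ is an unpenalized natural cubic regression spline (4 df,
knots at covariate quantiles) and month is a 12-level factor. As
$\sigma \to 0$ the variance collapses to the binomial $n\mu(1-\mu)$. Six
candidate structures (binomial vs beta-binomial; linear vs additive mean
terms; constant/linear/additive dispersion terms) are fitted by maximum
likelihood and ranked by AICc.

**Stage 2 — prediction model.** With fitted call probabilities
$p_E(s, m)$ and $p_W(s, m)$ at position $s$ and month $m$, the probability
that a catch belonged to the eastern population is

$$P_{E}(s, m) = \frac{p_E(s,m)}{p_E(s,m) + \lambda\, p_W(s,m)},$$

where $\lambda$ is the unknown scaling between the call-probability ratio
and the density ratio (base case $\lambda = 1$; sensitivity drawn
log-uniformly on $(0.5, 2)$, one draw per iteration).

**Uncertainty propagation.** Three sources are propagated by an ensemble
algorithm: (1) *catch uncertainty* — many records lack exact positions or
dates and are Monte Carlo imputed under five constraint categories
(exact, inferred, Soviet log rectangles, management-region donor pools,
same-expedition donor pools), with missing months drawn from donor month
frequencies within each expedition's operating period; (2) *statistical
uncertainty* — the acoustic station-month rows are bootstrap-resampled and
both occurrence models refitted (iterations where either refit fails to
converge are discarded and redrawn); (3) *ecological uncertainty* — the
$\lambda$ draw. Each iteration yields a split annual catch series with
exact conservation (ENP + WNP = conflated count per year); per-year
2.5/50/97.5 percentiles over iterations summarize the ensemble, and the
widths of the nested ensembles decompose the total uncertainty.

**Validation.** Western blue whales are longer than eastern ones. For each
iteration the mature-female catches are assigned hard labels at
probability 0.5 and compared by a Welch t-test on length; the predicted
probability is also regressed on length (a negative slope means longer
whales are less likely eastern).

## Worked example

```python
import callsplit as cs

# a synthetic North Pacific with known truth: 600 catches, 32 hydrophones
world, acoustic, catches, donors = cs.simulate_world(600, n_stations=32, seed=1)
east = acoustic[acoustic.call_type == "east"].reset_index(drop=True)
west = acoustic[acoustic.call_type == "west"].reset_index(drop=True)

fit = cs.fit_occurrence_model(east, cs.ModelStructure())
print(fit.summary())

model = cs.CatchSplitModel(
    catches, donors, east, west,
    cs.ModelStructure("beta_binomial", "additive", "constant"),
    bootstrap=True, lam_mode=("loguniform", (0.5, 2.0)))
ens = model.fit(200, seed=1)
print(ens.summary())
```

prints

```
Beta-binomial additive occurrence model
=======================================================
Structure:   Beta-Binomial / Additive / Additive
N obs:       290
df:          40
Log-lik:     -116762.787
AICc:        233618.747
Converged:   True
...

Catch split ensemble
=======================================================
Iterations retained:  200 of 200 attempts
Refit failures:       east 0, west 0
Bootstrap:            True
Lambda mode:          ('loguniform', (0.5, 2.0))
Assignment:           expected
-------------------------------------------------------
Total eastern catches: median 285 (95% range 232-343)
Years covered:         1905-1971
```

The occurrence model uses all 40 coefficients of the full structure
(intercept + two 4-df spatial splines + 11 month contrasts, on each of the
two distribution parameters). The ensemble's 95% range (232–343) covers
this world's true eastern total of 306, and every iteration conserves the
conflated counts exactly. `cs.aggregate_percentiles(ens)` yields the
per-year percentile table, and `cs.length_tests` /
`cs.summarize_validation` run the length validation on
`ens.probability_matrix()`.

A command line wraps the same pipeline:

```bash
callsplit simulate --seed 1 --catches 600 --out data/
callsplit run --acoustic data/acoustic.csv --catches data/catches.csv \
    --donors data/donors.csv --out results/ --iterations 200 --seed 1
callsplit report results/
```

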