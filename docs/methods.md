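# Methods

## Thermal-time model and estimation procedure

The package treats a seed lot as a population of individuals that differ in
their degree-day requirement θ but share one base temperature T_b. At a
constant sub-optimal incubation temperature T, the fraction-g percentile
germinates after t_g = θ_g / (T − T_b) days, so the germination rate 1/t_g
is linear in T and extrapolates to zero at T_b. This holds only between T_b
and the optimum T_o; above the optimum the rate declines, and beyond the
ceiling T_c germination stops. The pipeline therefore estimates three
things per condition (site × stratification): the sub-optimal temperature
range, T_b, and the θ_g profile.

Assumptions worth keeping in mind: percentile times come from **pooled**
curves (replicate dishes summed; per-dish percentile times would give a
different error structure); percentages are fractions of **filled** seeds
(cut-test empties excluded from the denominator, with a `basis="viable"`
switch that uses germinated + viable-ungerminated instead); and observation
binning means an interpolated t_g can never be earlier than the event but
can be up to one scoring interval later.

### Percentile times

Times to g = 10, 20, …, 90% are linearly interpolated on the cumulative
percentage axis, with the curve anchored at (day 0, 0%). A percentile above
the final percentage is recorded as not attained; a percentile exactly at
an observed value takes that observation's day (the earliest one, if the
curve plateaus there). Attainability, not a preset list, decides which
percentiles enter the fits: sparsely germinating conditions simply
contribute fewer percentiles.

### Sub-optimal range selection

Candidate upper temperatures default to every tested temperature from the
third-lowest upward that attains at least one percentile (with the standard
5–30 °C design this yields 15, 20, 25 °C — 30 °C never attains 10%). For
each candidate, every percentile with ≥3 (T, 1/t_g) points at temperatures
≤ the candidate is fitted by OLS; the candidate minimising the pooled
residual variance on the rate scale (ΣSSE / Σ(n_i − 2) across percentiles)
is chosen, ties going to the wider range. A `per_percentile=True` switch
averages per-percentile residual variances instead; it changes nothing on
exactly linear data and is provided for sensitivity checks.

### T_b and constrained θ

T_b is the mean of the x-intercepts (−intercept/slope) over the percentiles
whose OLS slope is positive and significant at α = 0.05 (classical
two-sided t test on the slope); its ± is the sample SD (n−1) across those
percentiles. Each percentile is then refitted constrained through T_b:
least squares through the origin of 1/t_g on (T − T_b), slope b = Σxy/Σx²,
θ_g = 1/b, using only points with T > T_b. θ50 is the g = 50 value. θ is
reported rounded to integer °Cd in tables; full precision is kept on the
estimate objects. Non-positive constrained slopes leave θ_g undefined for
that percentile (logged, not fatal). When no percentile regression is
significant the condition's T_b is reported unavailable — with short
stratifications this is the biologically expected outcome, not an error.

## Inferential statistics

Final proportions are modelled per dish with a binomial-family GLM (logit
link), filled seeds as prior weights, fitted by IRLS (tolerance 1e−8 on the
deviance, ≤100 iterations, via statsmodels). Quasi-likelihood enters
through the dispersion φ = Pearson χ² / residual df of the full model;
terms are tested sequentially (type-I): F = (Δdeviance/Δdf)/φ against
F(Δdf, residual df). Term order is stratification, temperature, site, then
the two- and three-way interactions, so each main effect is adjusted only
for those before it. If a model fits the data exactly (φ ≈ 0) the F tests
are reported as 0 with p = 1 for zero-deviance terms — there is no residual
variation to test against. Extreme coefficients (|β| > 15 on the logit
scale) raise a quasi-separation warning; with zero-germination cells in a
factorial design this is informative rather than fatal, since deviance
differences remain finite.

Pairwise pretreatment contrasts are two-sample t tests whose SD is pooled
across **all** levels (df = N − k), on per-dish percentages pooled over
temperatures and sites; raw p values are multiplied by the number of
comparisons and capped at 1. This collapses a strongly interacting design
onto one factor — it is the conventional summary for these experiments and
is kept configurable by simply passing a different grouping.

Base temperatures are compared across conditions with a quasi-Poisson GLM
(log link) on the per-percentile x-intercepts. A log link cannot accept the
negative x-intercepts that long-stratified lots produce, so when any value
is ≤0 the response is shifted by +(1 + |min|) first; the shift is recorded
on the result and flagged with a warning, because the comparison is then of
shifted means and the link is effectively a convenience, not a variance
model. This is the least-surprising way to make the analysis computable;
an identity-link alternative would be a reasonable substitute.

## Climate projection

Logger readings are averaged per calendar date (no imputation; missing
dates are logged). The dormancy-release criterion "soil at 1 ± 1 °C" is
operationalised as daily mean ≤ 2.0 °C — the band's upper edge — and
exposed as `threshold`. Counting windows default to consecutive
August–July years inside the series span (the natural seed year: dispersal
in August, winter, spring germination); a three-year series yields n = 3
windows behind each mean ± SD. Scenario increments are added to the raw
readings before averaging, which for an additive constant is identical to
shifting the daily means — hence the exact-identity property at Δ = 0 °C
and guaranteed monotone non-increasing counts in Δ. Cold days are counted
wherever they fall in the window (not required consecutive). The outcome
classes follow the stratification experiment: ≥60 days → full release,
30–60 → partial (roughly the germination a 30-day winter permits), <30 →
insufficient.

## What the synthetic generator emulates — and what it does not

The germination generator reproduces the statistical structure the
estimators assume: per-seed θ lognormal with median `theta50_true` and
log-SD `sigma_theta` (lognormal guarantees positivity; the within-lot
distribution is otherwise unconstrained by data), dormancy release
logistic in stratification days, empty seeds as an independent Bernoulli,
a rate plateau above `T_opt_hi` with the germinable fraction declining
linearly to zero at `T_ceiling`, and scoring on a discrete schedule (first
scoring day ≥ event). Defaults, chosen once to match the published
behaviour of the *G. lutea* seed lots:

| parameter | default | rationale |
|---|---|---|
| `T_b_true` | 0 °C | between the reported ~2–3 °C (60 d cold) and ~−2 °C (90 d) estimates |
| `theta50_true` | 120 °Cd | centre of the reported 108–130 °Cd range |
| `sigma_theta` | 0.15 | gives the observed within-condition spread of percentile times; no published value exists, this is a calibration choice |
| `T_opt_hi` | 20 °C | sub-optimal ranges reported up to 15–20 °C |
| `T_ceiling` | 27 °C | linear decline then gives ~29% germinable at 25 °C and 0 at 30 °C, the observed supra-optimal collapse |
| `strat_half`, `strat_slope` | 55 d, 12 d | logistic release ≈1/3/11/60/95% at 0/15/30/60/90 d, the published final-percentage ladder |
| `p_empty` | 0.10 | typical cut-test empty fraction for wild-collected lots |
| schedule | days 2, 4, 7 + weekly | thrice-weekly scoring to 98 d |

The generator deliberately omits features of real data: T_b does not vary
with stratification (the real lots show T_b falling as dormancy is
released — so the simulator cannot reproduce that contrast, only the
estimability pattern); there is no after-ripening, secondary dormancy,
seed mortality during incubation, or dish-level random effects beyond
binomial sampling. Passing tests therefore demonstrate that the estimators
recover the model they assume, not that the model captures every property
of laboratory data.

The soil generator is an annual sinusoid (mean 9.5 °C, amplitude 9.5 °C,
peak mid-July) plus a small diurnal cycle (1.5 °C — soil at ~3 cm is
strongly damped), AR(1) noise (SD 1.5 °C, lag-1 correlation 0.7 between
readings), and a snowpack clamp: any reading below −0.5 °C is replaced by
a uniform draw in [−0.5, 1.5] °C, producing the flat near-0 °C winter
plateau loggers show under snow. The annual geometry was set analytically
so the sinusoid sits ≤2 °C for ≈77 days per winter, the published current
cold-day count at these sites; there is no energy-balance snow model, so
interannual variability comes only from the noise.

All randomness flows from one root seed; each dish gets an independent,
deterministic substream (seed-sequence spawn keyed by dish index), so runs
are reproducible bit-for-bit and insensitive to vectorisation changes
within a dish.

## Numerical choices and degenerate inputs

- OLS via `scipy.stats.linregress`; origin-constrained slope by the
  closed form Σxy/Σx². Both are cross-checked in the test suite against
  brute-force grid minimisation of the SSE (agreement ≤1e−6).
- Percentile interpolation tolerance for "exactly attained" is 1e−9
  percentage points.
- Curves reject decreasing fractions beyond 1e−12 (guarding float noise in
  pooled division).
- Range-selection ties use a 1e−12 tolerance and resolve to the wider
  range.
- Dishes with zero filled seeds are excluded from percentages (logged); a
  condition with no filled seeds at all is an error.
- Scenario increments must be ≥0; windows wholly outside the series raise,
  partially covered windows are counted over the days present and logged.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the full factorial design (2 × 5 × 6 × 4 dishes of 25 seeds = 6,000 seeds),
a 10,000-seed-per-temperature sub-optimal experiment with quarter-day
scoring for parameter recovery, 100 one-year logger series for the
monotonicity property, and 200-replicate Monte-Carlo power checks for the
GLM effects. Parameter-recovery guarantees (|T̂_b − T_b| ≤ 0.5 °C, θ̂50
within 10%) are stated for that recovery regime — sub-optimal temperatures
only, `sigma_theta` ≤ 0.2, ≥1,000 seeds per temperature — and fixed seeds.
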