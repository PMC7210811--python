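# germtt — thermal-time analysis of seed germination

`germtt` is a Python toolkit for the thermal-time (degree-day) analysis of
seed-lot germination experiments, built around the workflow used to study
cold-requiring mountain species such as *Gentiana lutea* subsp. *lutea*:
seeds are cold-stratified for different durations (emulating winters of
different lengths), incubated across a range of constant temperatures, and
scored repeatedly; the package estimates the lot's thermal thresholds,
tests the dormancy-release effects, and projects whether future winters
will still be cold enough to release dormancy at all.

It is aimed at seed ecophysiologists and conservation scientists who have
germination time-courses and soil-logger series and want a tested,
scriptable pipeline instead of spreadsheet arithmetic.

## The model

For the fraction *g* of a seed lot, the time *t_g* to germinate at a
sub-optimal constant temperature *T* follows the thermal-time relation

    1 / t_g  =  (T − T_b) / θ_g

where *T_b* is the **base temperature** (°C) common to the lot — the
temperature at which the germination rate extrapolates to zero — and *θ_g*
is the percentile's **thermal time** (°Cd), the degree-days above *T_b* it
must accumulate. The pipeline:

1. pools the replicate dishes of each condition into a cumulative
   germination curve (fractions of *filled* seeds, i.e. excluding cut-test
   empties) and interpolates the percentile times *t_g* (g = 10…90%);
2. regresses 1/*t_g* on *T* per percentile by OLS, restricting to the
   sub-optimal range chosen by smallest pooled residual variance;
3. takes *T_b* as the mean (± SD) of the x-intercepts of the percentiles
   whose regressions are significant (p < 0.05), then refits each
   percentile constrained through *T_b* to obtain *θ_g* (θ50 at g = 50);
4. analyses final germination with a quasi-binomial GLM (logit link,
   sequential F tests on an empirical dispersion) and Bonferroni-adjusted
   pooled-SD pairwise t tests;
5. reduces soil-logger series to daily means, counts the days per
   August–July year at or below the dormancy-release band (daily mean
   ≤ 2.0 °C, the upper edge of 1 ± 1 °C), repeats the count after adding
   the IPCC RCP warming increments (+0.3 … +4.8 °C) and classifies the
   outcome (≥60 days → full release, 30–60 → partial, <30 → insufficient).

A synthetic-data module (`germtt.synthetic_data`) generates the full
factorial experiment and logger series from known ground truth (lognormal
θ across seeds, logistic dormancy release in stratification time, snowpack
clamp in winter), so every stage is testable against the values it should
recover.

## Worked example

```python
import germtt as gt

params = gt.SimulationParams(rng_seed=42)
records = gt.simulate_germination_experiment(gt.make_paper_design(), params)

summary = gt.summary_table(records)
print("minimum stratification for >50% germination:",
      gt.min_stratification_for_target(summary, 50.0), "days")

for est in gt.analyze_experiment(records):
    if est.available:
        print(f"{est.site} C{est.pretreatment_days}: "
              f"T_b = {est.T_b_mean:.2f} +/- {est.T_b_sd:.2f} degC, "
              f"theta50 = {est.theta50:.0f} degC d "
              f"(sub-optimal range up to {est.suboptimal_max:.0f} degC)")

series = gt.simulate_soil_temperature(gt.TempSeriesParams(rng_seed=42), site="IS")
for r in gt.apply_scenarios(series):
    if r.scenario in ("Current", "RCP2.6-OP", "RCP2.6-LOP", "RCP8.5-LOP"):
        print(f"{r.scenario:12s} +{r.delta_t:.1f} degC: "
              f"{r.mean:5.1f} +/- {r.sd:4.1f} cold days -> {r.outcome}")
```

prints

```
minimum stratification for >50% germination: 60 days
IS C60: T_b = 0.05 +/- 0.44 degC, theta50 = 139 degC d (sub-optimal range up to 15 degC)
IS C90: T_b = 0.39 +/- 0.57 degC, theta50 = 116 degC d (sub-optimal range up to 20 degC)
TM C60: T_b = -0.15 +/- 0.47 degC, theta50 = 136 degC d (sub-optimal range up to 15 degC)
TM C90: T_b = 0.39 +/- 0.26 degC, theta50 = 117 degC d (sub-optimal range up to 15 degC)
Current      +0.0 degC:  72.7 +/-  3.1 cold days -> full_release
RCP2.6-OP    +0.3 degC:  64.0 +/-  3.6 cold days -> full_release
RCP2.6-LOP   +1.7 degC:   7.3 +/-  5.9 cold days -> insufficient
RCP8.5-LOP   +4.8 degC:   0.0 +/-  0.0 cold days -> insufficient
```

Reading it: only lots stratified 60 days or longer cross 50% germination —
shorter "winters" leave most seeds dormant. The recovered base
temperatures sit around the generator's true 0 °C and the θ50 values
around the true 120 °Cd (with the C60 lots noisier, as fewer percentiles
are attained). The projection says a +0.3 °C winter still accumulates
enough near-0 °C days to release dormancy, while +1.7 °C already drops the
cold-day count far below the 30-day floor.

Dormancy biology, not the fitting, limits what is estimable: unstratified
and 15-day lots germinate too sparsely for any percentile regression, so
`analyze_experiment` reports their *T_b* as unavailable rather than
extrapolating.

## Command line

```bash
germtt simulate-germ --seed 1 --out germ.csv
germtt summary       --in germ.csv --out table1.csv
germtt thermal-time  --in germ.csv --alpha 0.05 --out thermal.csv
germtt stats         --in germ.csv --out stats/
germtt simulate-soil --seed 1 --out soil.csv
germtt project       --in soil.csv --site IS --threshold 2.0 --out cold_days.csv
```

The germination CSV dialect is long-format, one row per dish × observation:
`site, pretreatment_days, temperature_c, dish, day, cum_germinated, sown,
empty, viable_ungerminated` (the three cut-test counts repeated on each
row). Logger CSVs carry `timestamp` (ISO-8601 or DD/MM/YYYY HH:MM,
auto-detected) and `temperature_c`.

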