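# microcast

Does biodiversity make ecological dynamics harder or easier to forecast —
and does the answer change while the environment is changing? `microcast` is
a tested Python pipeline for that question in the setting where it can be
answered experimentally: long protist–algae microcosm time series (30
bottles × 123 Mon/Wed/Fri samplings over 41 weeks) crossing three species
richness levels (7/10/14 species from an 18-species pool in six functional
groups) with constant versus gradually declining light (30% → 1% of maximum
intensity over the middle three months).

It is aimed at ecologists studying forecastability — the package both
*generates* synthetic experiments with the relevant statistical structure
and *analyses* them (or any data in the same tidy layout):

1. **design** — species pool, maximally dissimilar community compositions,
   light schedules, the 123-date sampling calendar, the 30-bottle grid;
2. **simulate** — light-forced generalized Lotka–Volterra dynamics with 5%
   batch dilution per sampling, three-weekly immigration pulses, extinction
   thresholding, Poisson counting + lognormal observation noise, and
   instrument-specific missingness;
3. **preprocess** — monotone cubic Hermite imputation onto the uniform
   2.3-day grid, linear detrending and standardization (exact
   back-transformation to the original scale), realized richness;
4. **forecast** — one-step-ahead engines behind a common fit/predict
   interface: climatological mean baseline, Simplex projection with
   leave-one-out embedding-dimension selection, Multiview embedding
   ensembles, and an AICc-selected ARIMA grid, all trained on the first 111
   points and evaluated on the last 12 using observed history only;
5. **metrics** — RMSE on both scales, coefficient of variation, lag-5
   autocorrelation, normalized permutation entropy;
6. **inference** — REML random-intercept mixed models of forecast error on
   centered realized richness × light (random intercepts: taxon, bottle,
   incubator — or composition, incubator for aggregate properties), the
   p < 0.1 interaction screen switching between type III and type II Wald
   ANOVA, per-light slopes as percent change in forecast error per added
   species, post hoc light contrasts, and a multigroup recursive path model
   (richness and the three diagnostics explaining forecast error per light
   condition).

On standardized series the zero-anomaly forecast has RMSE exactly 1, so an
RMSE below 1 means skill beyond the series mean, and a mixed-model richness
slope of 0.056 reads as "+5.6% forecast error per added species".

## Worked example

```python
import numpy as np
from microcast import design as dz, simulate as sim
from microcast import pipeline as pl, inference as inf

pool = dz.SpeciesPool.default()
bottles = dz.build_bottle_grid(dz.assemble_compositions(pool, seed=0))
params = sim.SimParams.default_for_pool(pool)
raw, results = pl.run_experiment_tables(seed=1000, bottles=bottles,
                                        pool=pool, params=params)
fit, anova, slopes, full_fit = pl.analyze_taxa_errors(results)
print(f"taxa series forecast: {len(pl.taxa_table(results))}")
print(f"slope constant  {slopes['slope_constant']:+.3f} "
      f"({slopes['percent_change_constant']:+.1f}% per species)")
print(f"slope declining {slopes['slope_declining']:+.3f} "
      f"({slopes['percent_change_declining']:+.1f}% per species)")
print(f"interaction retained: {anova.interaction_retained}")
```

prints (seeds as above):

```
taxa series forecast: 194
slope constant  +0.009 (+0.9% per species)
slope declining -0.044 (-4.4% per species)
interaction retained: False
```

— the headline structure of the synthetic experiment: richness *raises* the
forecast error of taxa abundances under constant light and *lowers* it when
light declines (here the interaction screen, at p ≥ 0.1, still drops the
weak interaction; across replicates the opposite-signed slopes are the
stable feature). `full_fit.summary()` shows the coefficient table;
`pl.fit_sem(results).summary()` prints the per-light-condition path model.

A thin CLI wraps the same stages:

```
microcast design --seed 0 --out design.yaml
microcast simulate --design design.yaml --seed 1 --out raw.csv
microcast run --seed 1 --out results.csv
microcast infer --results results.csv --out inference.json
```

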