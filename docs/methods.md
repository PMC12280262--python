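# Methods

`microcast` studies a single question on fully synthetic data: how do species
richness and gradual environmental (light) change affect the one-step-ahead
forecastability of population and ecosystem time series in a microcosm
experiment? This note documents the models, the choices behind them, and what
the synthetic data can and cannot show.

## Experimental design encoded

The design module fixes the study layout: an 18-species pool of algae and
ciliates in six functional groups (2 edible algae, 5 inedible algae, 4
bacterivores, 4 omnivores, 2 mixotrophs, 1 predator); three richness levels
(7, 10, 14 species) built by varying the number of species per functional
group; five compositions per level, chosen by a greedy maximin search on
pairwise Jaccard dissimilarity with usage balancing (exhaustive optimisation
over all assignments is combinatorially unnecessary — candidate sets per
level number only a few hundred, and the greedy solution already beats random
assignment on mean pairwise similarity, which a test verifies statistically).
Each composition is run under two light regimes (30 bottles), with four
incubators per regime assigned round-robin. Sampling is Mon/Wed/Fri for 41
weeks: 123 dates spanning 284 days, giving a uniform analysis grid of
284/122 ≈ 2.33 days (printed as 2.3).

The declining-light regime is three phases of 91 days — constant 30% of
maximum intensity, a ramp down to 1%, then constant 1%. The ramp is linear in
percent per day: the protocol only requires a gradual monotone decline, and
linear is the simplest such interpolation. Three 91-day phases tile the
284-day span with 11 days left in the final phase.

## Community simulator

Latent dynamics are generalized Lotka–Volterra with light forcing:

    dN_i/dt = N_i [ r_i(L(t)) + Σ_j A_ij N_j + ε_i(t) ],

where light-dependent taxa (algae, mixotrophs) have
r_i(L) = r_max,i · L/(L+K_L,i) · N/(N+K_N) and heterotrophs have r_i = −m_i.
The trophic skeleton follows the functional groups: producers compete;
bacterivores, omnivores and mixotrophs graze bacteria; omnivores also eat
edible algae, with a diet spread from algae-leaning to bacteria-leaning
members so richer communities contain consumers that tolerate an algal
collapse; the predator eats ciliates. Bacteria grow on dissolved organic
carbon, which is supplied basally (wheat seeds) and by algal exudation — the
channel through which the light treatment reaches the heterotrophic food
web. Nutrients and DOC follow chemostat-style refresh toward fresh-medium
levels at each dilution. Per-species rates carry lognormal jitter around
group-level baselines; light half-saturation constants are spread within the
inedible algae (2–14% of maximum light) and mixotrophs so richer communities
span sensitive and tolerant variants.

Discrete events at each sampling: the observation is recorded pre-dilution;
5% of the volume is replaced (N ← 0.95·N, nutrients refreshed); taxa below
10⁻³ individuals/mL go extinct (preventing nano-population immortality
between dilutions); every 9th sampling (three weeks) each member taxon with
a living stock culture receives 10 individuals per bottle. Two ciliates are
flagged as lost from the stocks and never re-immigrate. Integration is
fixed-step RK4 at 0.05 days between events — the rates are modest, the
events are discontinuous, and a stiff adaptive solver would buy nothing.

### Environmental perturbations and the insurance structure

ε_i(t) is a per-sampling-interval growth-rate perturbation (default SD
0.13/day) with a structure that encodes the insurance effect of functional
redundancy, the mechanism the analysis is designed to detect:

- While the environment is stable, populations track temporally
  autocorrelated micro-environmental fluctuation: for functionally
  *unbuffered* populations (few or no partners in their group) the
  perturbation is mostly a persistent AR(1) component (coefficient 0.9),
  producing smooth, predictable dynamics in species-poor communities.
- Functional redundancy damps this tracking (compensation within the group
  absorbs environmental variation): with the default damping of 0.7, a
  fully buffered population retains 30% of the perturbation amplitude.
- When light departs from its initial level, smooth tracking degrades.
  Unbuffered populations respond erratically — white perturbations amplified
  up to 8-fold at the full light deficit ("novel dynamics"); buffered
  populations degrade gracefully into slow persistent responses.

The observation layer adds Poisson counting error from finite counted
volumes (0.02 mL FlowCAM for algae, 0.2 mL video for ciliates, 10⁻⁴ mL flow
cytometry for bacteria) — counting noise is relatively larger at low
density, and per-species densities fall with richness in a substitutive
design — followed by multiplicative lognormal noise (CV 0.12; abundances
span orders of magnitude, so variance grows with the mean) and
instrument-specific missingness (FlowCAM 0.81%, flow cytometer 4.84%, video
0.84%, oxygen meter 1.67%, TOC/TN 0.92%). Oxygen is an instantaneous balance,
baseline + α·(photosynthesis) − β·(respiration biomass), with additive
noise. Community biomass sums observed constituent biomasses (biovolume ×
10⁻⁶ µg/µm³) and is missing whenever a constituent is.

These perturbation and counting parameters were calibrated so the generated
data reproduce the qualitative treatment directions the analysis targets:
higher lag-5 autocorrelation under declining light, and richness slopes on
forecast error of opposite sign in the two light regimes (positive under
constant, negative under declining light). The calibration fixes the study
conditions; tests and the acceptance script run against these defaults.

What the simulator does **not** emulate: mechanistic protist bioenergetics,
bacterial community composition, instrument drift, classification error
between morphologically similar taxa, or any fit to real microcosm data.
Passing tests therefore show that the *pipeline* behaves correctly on data
with the assumed statistical structure, not that real communities have that
structure.

## Preprocessing

Missing values are imputed and the irregular calendar regridded in one step
with a shape-preserving piecewise-cubic Hermite interpolant (Fritsch–Carlson
monotone slopes — plain cubic splines overshoot on spiky abundance series
and can produce negative abundances). Leading/trailing missing values are
replaced by the nearest observed value before fitting; extrapolating cubics
is unstable. Observed points on grid nodes are reproduced exactly, and the
interpolant never leaves the range of neighbouring observations.

Each regridded series is detrended by OLS against the grid index (linear
trend: the minimal stationarity-making choice, and the one that keeps the
back-transformation algebra exact) and divided by the *population* SD of the
window residuals. With the full window this makes the standardized series
mean-0/SD-1 exactly, so the climatological zero-anomaly forecast has RMSE
exactly 1 — the natural skill baseline. A training-only variant fits trend
and scale on the first 111 points and extrapolates. No log-transformation
precedes detrending. `back_transform` inverts the transformation exactly at
every grid index. The regression uses the grid index rather than the
calendar date; the two differ only in slope units.

Realized richness is the median over dates of the number of member taxa
present (threshold 0 by default, configurable for noisy observations).

## Forecasting

All engines train on points 1–111 and forecast points 112–123 one step
ahead, always conditioning on observed (never predicted) history:

- **mean** — predicts the zero anomaly; RMSE 1 on a full-window standardized
  series by construction.
- **simplex** — delay-embedding nearest-neighbour projection: the E+1
  nearest library states vote with weights exp(−d/d_min); an exact match
  short-circuits to the mean of zero-distance successors. E ∈ 1..8 is chosen
  by leave-one-out one-step skill within the training window with a Theiler
  exclusion window of E steps (no self-matching). The library is frozen at
  the training window so every engine sees the same information set; a
  growing-library variant is available behind a flag.
- **multiview** — candidate views are all size-3 combinations of lagged
  coordinates (lags 0–2) over the bottle's predictor set (all taxa targets
  plus dissolved carbon and nitrogen), each containing at least one target
  coordinate; views are ranked by in-train leave-one-out simplex RMSE and
  the top ⌈√(#views)⌉ predictions are averaged. Above 5000 candidates the
  set is subsampled uniformly (seeded).
- **arima** — ARIMA(p,0,q), p,q ≤ 3, by Gaussian ML on the training window,
  selected by AICc; d = 0 because detrending precedes forecasting. Test
  predictions come from applying the frozen parameters to the observed
  series. If nothing converges the engine falls back to AR(1) with a
  warning.

Distances are Euclidean on standardized coordinates. Engines implement a
common fit/predict interface, so additional learners (e.g. tree ensembles)
can be slotted in without touching the protocol. Forecast error is RMSE on
the standardized scale and, via the exact back-transformation, on the
original scale.

## Diagnostics

Per series: coefficient of variation (SD of the detrended-but-
unstandardized residuals over the mean of the original series — dividing
after standardization would give 1/mean identically), lag-5 autocorrelation,
and normalized permutation entropy of order m = 3 (123 points give ~121
windows; m = 4 would undersample its 24 patterns). Ties in ordinal patterns
break by temporal order. ac5 and PE are computed on the transformed series.

## Treatment-effect inference

Forecast error is modelled with REML random-intercept linear mixed models:
taxa-level responses get random intercepts for taxon, bottle and incubator;
aggregate responses (biomass, oxygen) for composition and incubator.
Realized richness enters centered at its mean over bottles. Wald t tests and
Wald 95% CIs use a residual-based denominator df (n − rank(X));
profile-likelihood intervals are deliberately not implemented, with the
caveat that Wald and profile intervals can disagree when evidence is weak.
Zero variance components are reported as singular fits with a warning, not
errors — expected with 4–8 incubators.

The interaction decision rule: fit with the richness × light interaction and
test it with a type III Wald F (sum-to-zero contrasts for light); retain it
and report type III for all terms iff p < 0.1, otherwise refit without it
and report type II main-effect tests (which coincide with per-term Wald
tests in the additive model). Slopes per light condition come from the
treatment-coded fit (constant light as reference): slope_constant = β_rich,
slope_declining = β_rich + β_interaction; on standardized series the
baseline error is 1, so 100·slope is the percent change per added species.
Post hoc light contrasts at chosen richness values use the fixed-effect
covariance. The aggregation-level model stacks per-bottle mean taxa error
with the aggregate error, fits all pairwise interactions with bottle and
incubator intercepts, and applies the same screen jointly (any interaction
p < 0.1 keeps them all with type III).

## Path analysis

A multigroup recursive path model (groups = light conditions) relates
richness, the three diagnostics and forecast error: richness → each
diagnostic, and richness + diagnostics → error, with free residual
covariances among the diagnostics. Equations are estimated by least squares
within group — ML-equivalent for recursive observed-variable models — and
the global statistic is χ² = Σ_g (N_g−1)·F_ML comparing model-implied and
sample (ML, ÷n) covariances; df = moments − free parameters summed over
groups. The default structure is exactly saturated per group (15 parameters
= 15 moments), so its χ² is 0 with df 0 and the fit is reported
transparently rather than constrained across groups; restricted structures
(dropping paths or covariances) yield positive df. No cluster/survey
adjustment of the standard errors is applied; the bottle/incubator structure
is ignored at this stage, which is a documented limitation.

## Problem sizes in the checks

The test suite and acceptance script use the design's native sizes: 123-point
series, 111/12 train/test, 30-bottle experiments. Replicated calibration
checks use 500 replicates (CI coverage), 200 (decision-rule level), 10
(end-to-end directional reproduction), and benchmark ensembles of 20–100
series — sizes at which the binomial/Monte-Carlo error of each check is
comfortably below the tolerance it asserts.

## Known limitations

- The richness × light interaction in the generator is phenomenological
  (perturbation buffering + counting noise), not an emergent property of the
  gLV core; the pipeline detects it, it does not explain it.
- Wald inference with 8 incubators is slightly anti-conservative; no
  small-sample (Kenward–Roger/Satterthwaite) correction is implemented.
- The SEM ignores the clustered design.
- Random-forest and recurrent-network engines are not implemented; the
  forecaster interface reserves the slot.
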