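# elevgrad

Where along a mountain gradient do threatened species concentrate, and how
much of that pattern is geometry rather than ecology? `elevgrad` is an
analysis pipeline for threatened-species richness along an elevational
gradient, built for conservation biogeographers working with band-level
data (the Nepal Himalaya, 0–4900 m, in 100-m bands, is the motivating
system). It provides:

- **Range interpolation** — species elevational ranges binned onto 49
  half-open 100-m bands (floor the lower limit, ceil the upper), with
  per-band richness and mean range size;
- **Undersampling sensitivity** — deterministic range augmentation by
  range-size category (< 1300 m, 1300–2550 m, > 2550 m) under three
  scenarios (20/10/0%, 30/20/10%, 50/25/10% of the 5000 m gradient),
  clamped to 67–4900 m, compared to the empirical pattern with
  Bonferroni-corrected Pearson tests;
- **Mid-domain-effect null model** — 5000 Monte Carlo simulations without
  replacement of the empirical range sizes, midpoints uniform between the
  hard boundaries, yielding per-band expected richness
  `E[S_b] = Σ_i P(band b ⊂ placement of range R_i)` with a 95% envelope;
- **Spatially correlated inference** — GLS with residual correlation
  `corr(d) = exp(−(d/ρ)²)` (also exponential and spherical) profiled by
  maximum likelihood over ρ, AIC structure selection, likelihood-ratio term
  tests, VIF screening, quasi-Poisson sequential analysis of deviance, and
  fixed-df natural-spline smooths;
- **A synthetic-community generator** with known ground truth (range-size
  distribution, midpoint bias, covariate decay, and a logistic threat
  mechanism in log range size × log human density) for validating every
  stage.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
community and write their tables under `results/`:

```sh
python analysis/01_simulate_community.py
python analysis/02_band_richness.py
python analysis/03_augmentation_sensitivity.py
python analysis/04_mde_null_model.py
python analysis/05_regression_inference.py
```

Output from a run (seed 42):

```
community: 71-species pool, 39 threatened (39 rows written)
...
richness peaks at the 400 m band (n = 15); mean richness 10.8 in the
lowest third vs 0.9 in the highest third
...
  empirical vs S1: r = 0.91, adjusted p = 4.36e-19
  empirical vs S2: r = 0.91, adjusted p = 1.19e-18
  empirical vs S3: r = 0.85, adjusted p = 7.85e-14
...
simulated vs empirical per-band range size: Spearman rho = 0.34 (p = 0.0259)
...
bands in the GLS: 43 (6 zero-richness bands dropped)
best correlation structure by AIC: spherical (rho = 716 m)
GLS coefficients (standardized design):
  range_size                          -0.445
  population_density                  -0.041
  ...
single-term-deletion likelihood-ratio tests:
  range_size                          chi2(1) =   7.45, p = 0.00634
```

Reading this: the threatened subset concentrates at low elevations (richness
10.8 vs 0.9 between the lowest and highest thirds of the gradient);
augmented richness patterns stay strongly correlated with the empirical one,
so interpolation undersampling does not drive the shape; and after AIC
selection of the residual correlation structure, mean range size is the
clearest band-level correlate of richness (negative, as built into the
generator's threat mechanism).

The same stages are scriptable through the `elevgrad` CLI
(`simulate`, `grid`, `augment`, `null`, `fit`, `report`), e.g.

```sh
elevgrad augment --scenario S1 --species species.csv --out augmented.csv
elevgrad null --species species.csv --sims 5000 --seed 42 --out null.csv
```

A species with range 200–1400 m (size 1200 m, category a) under scenario S1
is extended by 20% of the gradient (±500 m) and clamped below at 67 m,
giving 67–1900 m — the reference case for the augmentation arithmetic.

## Layout

```
src/elevgrad/        domain_io, gridding, augmentation, mde_null, stats,
                     synthetic_data, pipeline, cli
analysis/            numbered narrative drivers (simulate → ... → inference)
tests/               pytest suite incl. independent oracles
docs/methods.md      model, assumptions, defaults, limitations
```
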