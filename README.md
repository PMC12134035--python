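# dormouse-torpor

Analysis pipeline for **short torpor use in hazel dormice** (*Muscardinus
avellanarius*) from nest-box monitoring data. During the active season
(April–October) dormice enter short (< 24 h) torpor bouts; how often they do
so varies among sites, months, sexes and weather conditions, and may relate
to local population performance. This package implements that analysis
chain for data of the kind collected by long-running volunteer monitoring
schemes — and, because such data are restricted, ships a synthetic-data
generator with known ground truth so every stage is testable end to end.

The pipeline has five stages, driven by the numbered scripts in
`analysis/` over the library in `src/dormouse_torpor/`:

1. **Site torpor index** — a binomial GLM `torpid ~ site + month + year + sex`
   (logit link); each site's treatment-coded coefficient βₛ, inverse-logit
   transformed, is that site's index in (0, 1). The reference site (nearest
   the mean coordinate of all sites) has βₛ = 0, hence index exactly 0.5.
   Sites that never recorded torpor receive a single "dummy" torpid record
   at their earliest survey date before fitting, so no site is fitted with
   an unrealistically zero probability.
2. **Environmental correlates** — all-subsets ("dredge") Gaussian models of
   the site index on site covariates (location, elevation, solar index,
   habitat, connectivity); the top set is every model within 2 AIC of the
   best, a variable's importance is the fraction of top-set models that
   contain it, and coefficients are Akaike-weight averaged over the set.
3. **Individual torpor model** — a binomial GLM with complementary log-log
   link (chosen for the asymmetric torpid/active split),
   `torpid ~ month * (mass + sex) + box context + weather`, where weather
   enters as daily/weekly/monthly/seasonal (1/7/30/90-day) means of minimum
   temperature and rainfall totals, each a residual from a 30-year
   day-of-year baseline. Under cloglog, a covariate shift Δ multiplies the
   hazard by exp(βΔ), so a baseline probability p₀ maps to
   p₁ = 1 − (1 − p₀)^exp(βΔ); exp(β) is reported as a hazard ratio.
   Validation is by ROC/AUC.
4. **Yearly torpor scores** — per sex (and per early/late season split),
   `torpid ~ site * year` (saturated cell model); the inverse-logit of each
   observed site-year cell's linear predictor is that cell's score in [0, 1].
5. **Population effects** — site-year metrics (adult counts, young counts,
   breeding events, litter size, masses) modelled on female and male scores
   (Poisson log for counts, Gaussian for masses), same-year and next-year;
   effects are reported as the percentage change in the predicted response
   between score 0 and score 1.

All GLM machinery (IRLS with step-halving, Wald inference, AIC,
response-scale prediction intervals, hazard ratios, ROC/AUC) is implemented
in `dormouse_torpor.glm`; statsmodels appears only as an independent test
oracle.

## Worked example

```sh
python analysis/01_simulate_dataset.py --seed 20260929
python analysis/02_clean_records.py
python analysis/03_site_index_environment.py
python analysis/04_individual_torpor_model.py
python analysis/05_population_effects.py
```

The first run prints

```
wrote 19182 records for 40 sites x 10 years to results/data/
  adult records: 13492, torpid fraction 0.247 (generator anchored near 0.23)
```

— the generator draws torpid states from a cloglog model anchored so that
roughly 23% of adult records are torpid. Stage 3 then reports

```
site torpor index for 40 sites (reference S007 = 0.5, 0 dummy records)
  index range 0.199 - 0.935, mean 0.563
dredge: 256 models, top set (delta <= 2.0) holds 6
  best model: index ~ longitude + elevation_scaled + prop_ancient
  longitude                    importance 1.00  avg coef -0.0367
  elevation_scaled             importance 1.00  avg coef +0.0490
  prop_ancient                 importance 1.00  avg coef +0.2583
```

recovering the generator's built-in pattern (more torpor to the west, at
elevation and in ancient woodland). Stage 4 fits the individual cloglog
model (e.g. daily-temperature hazard ratio ≈ 0.91 here: each +1 °C above
baseline multiplies the torpor hazard by ~0.91), and stage 5 prints the
effect matrix, e.g.

```
  [-] young_count            F score 0->1: -39.4% (95% CI -53.0 to -21.9)
```

i.e. site-years with ubiquitous female torpor have ~39% fewer young than
torpor-free ones — an emergent consequence of the generator's strong
torpor suppression in breeding boxes.

## Layout

- `src/dormouse_torpor/` — library: `data_model` (records, CSV I/O,
  filtering rules), `synthetic_data` (generator), `glm` (model core),
  `covariates` (climate windows, solar index), `torpor_index`,
  `model_selection` (dredge), `population_effects`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations.
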