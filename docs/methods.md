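# Methods

This note records the models, the choices made where the design was open,
and what the synthetic data do and do not establish.

## Data model and filtering

The unit of analysis is one dormouse record from one nest-box check:
site, box, date, sex, age class, mass (g), torpid state (0/1), and the
box's social context (counts of adults, juveniles and dependent young).
Animals are unmarked, so every per-site threshold counts *records*, not
individuals.

Two cleaned datasets are derived. Both apply the record-level rules, in
order: drop non-adults (juveniles enter torpor less and would dilute the
signal), drop records missing any of sex/mass/torpid, drop erroneous
(negative) masses, keep April–October only (November–March records are
hibernation or out-of-season activity), keep programme years (≥ 1993 by
default). The *site* dataset then drops sites with fewer than 15 retained
records; the *individual* dataset instead requires mass strictly above
10 g (lower masses are treated as recording errors; the boundary 10.0 g is
excluded) and at least 2 records per site. The record-level rules commute
(property-tested); the site-count rule is applied last, on the filtered
records. Each cleaner returns a report whose per-rule counts reconcile
exactly with input/output sizes, and both cleaners are idempotent.

A month or year column that conflicts with the record's date is an error,
never silently fixed. Time of day is not modelled; it is part of residual
variation.

## GLM core

`dormouse_torpor.glm` implements binomial (logit, cloglog), Gaussian and
Poisson GLMs by IRLS with step-halving: a step that would lower the
log-likelihood is halved until it does not, so the likelihood never
decreases across accepted iterations. Convergence requires both a relative
log-likelihood change below 1e-11 and a relative coefficient change below
1e-9 (tight enough that coefficients agree with an established
implementation to ~1e-8 on small data). The Gaussian family is solved
exactly by least squares.

Design matrices use treatment (dummy) coding against declared reference
levels. Structural rank deficiency is detected by pivoted QR and raises an
error naming the collinear columns; fits that must tolerate aliasing (the
saturated site×year model with empty cells, effect models with a constant
score) pass `allow_aliased=True`, which drops aliased columns as R's `glm`
does.

Inference is Wald: standard errors from the inverse Fisher information,
p-values from the normal reference. AIC is −2ℓ + 2p with the full
log-likelihood including constants; for the Gaussian family ℓ uses the MLE
scale σ̂² = RSS/n and p counts mean coefficients only (constant across a
dredge, so only differences matter). Prediction intervals are computed on
the linear-predictor scale and mapped through the inverse link, which
keeps probabilities in [0, 1] and preserves ordering; whether published
intervals were Wald or otherwise is generally unstated, and Wald is the
choice here.

Fits whose largest |β| exceeds 15 are flagged as separated (fitted
probabilities pinned at 0/1 within clipping); downstream consumers treat
such coefficients as capped rather than meaningful.

ROC curves sweep every distinct score as a threshold and integrate by the
trapezoid rule; tied scores collapse to one vertex, so the area equals the
Mann–Whitney rank statistic exactly (tested to 1e-12).

## Site torpor index

`torpid ~ site + month + year + sex`, all factors, logit link. The index
is the inverse-logit of the site's treatment-coded coefficient with
month/year/sex at reference levels — a relative quantity against the
reference site, which scores exactly 0.5. The reference is the site
nearest (great-circle) the mean latitude/longitude, ties broken by lowest
site id. Year is treated as categorical, matching its role as a nuisance
factor. The dummy-record rule (one torpid record at the earliest survey
date of an otherwise torpor-free site) prevents separation driving site
coefficients to −∞.

## Yearly sex/season scores

Per sex, `torpid ~ site * year` (both factors) is the saturated cell
model, so each observed cell's fitted probability is its raw torpid
proportion — the property the acceptance suite checks exhaustively on
small grids. The score is the inverse-logit of the *cell linear predictor*
(main effects + interaction), not of the bare interaction coefficient:
only the cell predictor yields a quantity interpretable per cell on the
0–1 "no torpor to always torpid" scale. Early-season scores use April–July
records, late-season August–October. The dummy rule is applied per fit to
torpor-free sites within the subset. Unsampled cells are absent, never
extrapolated. Because saturated fits separate wherever a cell is all-torpid
or torpor-free, these fits run with a capped iteration count (35), which
pins degenerate cells below 0.01 / above 0.99 without chasing divergent
coefficients.

## Environmental model selection

Gaussian models of the site index on up to 20 candidate site covariates,
fitted for every subset (intercept always present). The top set is every
model within 2 AIC of the best. Importance is the *unweighted proportion*
of top-set models containing the variable — the statistic as reported in
this literature — not the sum-of-Akaike-weights convention. Averaged
coefficients use full model averaging (a model omitting a variable
contributes zero) with Akaike weights renormalised within the top set;
full versus conditional averaging is not identifiable from published
summaries, and full averaging is the conservative choice. AIC (not AICc)
is used; elevation is the only standardised covariate (centred and scaled
across sites), the others enter on their natural scales.

## Climate windows and solar index

Weather covariates are means (temperature) or totals (rainfall) over
windows of 1, 7, 30 and 90 days ending on and including the observation
date, expressed as residuals from a 30-year day-of-year baseline
aggregated over the same window. For means this equals aggregating daily
residuals; for totals it equals total-minus-baseline-total. The "daily"
residual uses the observation day itself. On leap years, 29 February maps
to the 28 February baseline value.

The solar index is the proportion of direct beam received by the site's
mean slope/aspect surface at 12:00 solar time on the first day of each
month (non-leap day-of-year), averaged over the twelve months: each month
contributes max(0, cos θᵢ), where cos θᵢ = cos β sin h + sin β cos h
cos(A_sun − A_aspect), and contributes 0 when the sun is below the
horizon. Declination uses δ = 23.44° sin(360°(284+N)/365). Simplifications
relative to a full micro-climate model: no terrain horizon shading, no
diffuse component, and solar time is used without longitude or
equation-of-time corrections — the index is a relative site descriptor,
and these corrections are common to all sites at the precision used.

## Synthetic data generator

The generator emulates the structure of national nest-box monitoring: by
default 40 sites over 10 years, 5 visits per site-year (months drawn
without replacement from April–October), 50 boxes per site with ~10%
occupancy per visit. Occupied boxes hold 1 + Poisson(0.35) adults,
dependent-young litters (probability 0.18 in June–September, litter size
1 + Poisson(2.5), four age grades with greys-eyes-open commonest) and
late-season juveniles. Adult mass is Normal(17 + 0.5·(month − 4), 2.5) g —
heavier late in the season, so the mass×month sign flip is reproducible.

Weather per site-day: minimum temperature = seasonal sinusoid (mean 6 °C,
amplitude 6.5 °C, peak day 200) + Gaussian site offset (sd 0.8 °C) +
daily noise (sd 2.8 °C); rainfall is Bernoulli(0.45) wet days with
Gamma(0.7, 6 mm) amounts. The baseline table holds the deterministic
expectations, standing in for a 30-year mean series.

Adult torpid states are Bernoulli draws from a cloglog linear predictor
built by the same design machinery the fitting uses, with named true
coefficients (unnamed design columns are true zeros — the weekly/monthly
weather windows and the count of young, mirroring effects found negligible
in the field). Signs and magnitudes follow the field pattern: torpor
rarer late-season, in heavier animals (early), in males, in occupied and
breeding boxes, on warm days; commoner on wet days. The intercept (0.15)
anchors the realised overall torpid fraction near the 23% frequency these
schemes observe. Site heterogeneity is a Gaussian offset (sd 0.6) on the
linear predictor whose mean depends on centred site attributes (west,
high, ancient, well-connected sites lean torpid), giving the site-index
and dredge stages a recoverable signal; setting the coefficient map to
`{}` and the sd to 0 yields exchangeable sites. A 1% missingness rate on
sex/mass/torpid and a 0.2% negative-mass rate give the cleaning rules
realistic work.

What the generator does **not** emulate: spatially correlated weather,
box fidelity or capture histories of individuals (animals are unmarked),
density dependence, observer effects, and any direct causal path from
torpor to demography — the young-count "effects" in stage 5 are emergent
associations via the breeding-box term. Passing tests therefore establish
that the estimators recover known generating processes of this structure,
not that the field conclusions themselves are reproduced.

## Population effects

Site-year metrics are deterministic aggregations (early + late adult
counts always sum to the total; litter size is the mean young per breeding
box-visit; young mass uses the greys-eyes-open grade only). The abundance
and trend indices are simple effort-controlled surrogates, named as such
in outputs: mean over years of log10(1 + adults per box-visit), and the
per-site OLS slope of log(1 + yearly adult count) on year (sites with ≥ 3
surveyed years). The originals derive from a state-space trend framework
that the underlying publications describe only by reference; the
surrogates preserve the effort control and the log scale, which is what
the torpor-index regression consumes.

Effect models: each metric on female + male scores jointly, Poisson
log-link for counts and Gaussian identity for masses/litter size
(overridable — the published model structures live in supplementary
material that is not part of the available text, so families are exposed
as configuration). Lag-1 joins scores in year T to responses in year T+1.
The score-0 → 1 percent change is 100(exp β − 1) under the log link
(identical to the prediction-ratio computation, tested to 1e-10) and
100 β / intercept under the identity link, with CIs from the coefficient's
Wald interval; the comparison holds the other sex's score at 0.

## Problem sizes

Default analysis scale (40 sites × 10 years, ~13,500 adult records) runs
the full pipeline in about a minute. The parameter-recovery experiment
uses 200 replicates of ~20,000 adult records each (20 sites × 4 years ×
150 boxes at 25% occupancy) with site heterogeneity switched off so the
generating fixed-effects model is exactly the fitted model; each true
coefficient's 95% Wald CI coverage is required to sit within a 3σ binomial
band of 0.95. The null dredge calibration uses 3 candidate covariates at
n = 200 over 100 replicates.

## Known limitations

- No mixed models: site enters as a fixed factor (as in the source
  analyses); unmodelled heterogeneity attenuates individual-model
  coefficients when present.
- Wald inference throughout; no profile or simulation intervals.
- The Gaussian percent-change CI ignores intercept uncertainty.
- The solar index is unobstructed-beam only.
- Dredge is exhaustive and therefore capped at 20 candidates.
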