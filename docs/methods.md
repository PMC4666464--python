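# Methods

`gillnetkit` quantifies an illegal gillnet fishery from three indirect
lines of evidence — derelict gear washed up on the shoreline, a
standardized multi-mesh gillnet monitoring survey, and a data-poor stock
assessment — and asks whether plausible levels of covert effort could
exceed the target stock's sustainable harvest.

## Derelict-gear densities

Shoreline transects of varying width are censused for gear, so density is
linear: items (or grams) per km of shoreline. Items are classified into
gillnet categories (whole net, net fragment, float line, lead line, foam
float, bottle float) and hook-and-line categories (rod, monofilament,
lure, bobber); bottles, string/rope and stakes carrying no mesh, floats,
weights or lines are ordinary debris, not gear. Pooled densities weight
each transect by its length, so the pooled value is exactly total items
over total kilometres — an invariant the tests exercise under arbitrary
transect splits. Mesh composition of net material uses half-open 1-cm
bins over 2–8 cm by default (the range beach-cast gillnet debris spans);
edges are configurable. Between-year re-accumulation at re-surveyed
(previously cleared) sites is reported as per-site difference and ratio;
a zero baseline yields a flagged undefined ratio, never infinity, so one
site cannot poison a summary. Items lacking a weight measurement count
toward count densities and are excluded from weight densities with a
logged tally.

## CPUE and trend testing

Effort is counted in net-nights: a set soaked overnight is one night
whether it fished 8.5 or 10.5 hours. Panel CPUE is count (or kg) × (10 m
/ panel length) / nights; set CPUE is the panel total / nights.
Zero-catch panels and sets are retained as zeros — dropping them biases
both mesh comparisons and trends. The optimal mesh is the one with the
highest mean CPUE under a count or biomass criterion, ties breaking to
the smaller mesh.

Missing fish weights are imputed from a species-specific allometric fit,
W = a·L^b, estimated by least squares on log W vs log L (a
back-transformed from the intercept). Imputed weights enter biomass CPUE
but are excluded (via the `weight_imputed` flag) from body-size trend
input by default, because an imputed weight is a deterministic function
of length and would recycle the length signal.

Year trends are fitted as `response ~ year` with a random intercept per
site, by full maximum likelihood (not REML — the fixed effects differ
between the nested models being compared). Significance is a likelihood
ratio test against the intercept-plus-random-intercept null, referred to
a 1-df chi-square. Year is centred at the first survey year for
numerical conditioning; slope and p-value are invariant to the shift.
Abundance is modelled on the raw CPUE scale (mirroring how such survey
trends are usually displayed), with a `log1p` option for robustness
checks. With a single site the model degrades to fixed-intercept OLS
with a logged warning. Simulation tests show the LRT is close to nominal
on this design (type-I ≈ 0.04–0.06 at α = 0.05 across the calibration
runs the suite performs) and has power ≈ 1 against a 10%-per-year decline
once the design is scaled fourfold.

## Data-poor assessment chain

**Growth.** Von Bertalanffy, L(t) = L∞(1 − e^(−K(t−t0))), fitted by
nonlinear least squares; `anchor_origin` fixes t0 = 0 so the curve passes
through the origin, the right constraint when young ages are missing from
gear-selected samples.

**Total mortality.** A length-converted catch curve: lengths are binned
(10 mm default), each bin mapped to the relative age of its midpoint
length by the inverse growth curve t = t0 − (1/K)·ln(1 − L/L∞), and
ln(count/Δt) regressed on relative age; Z is the negative slope, with the
regression SE attached. The trailing arm comprises bins strictly after
the modal bin, excluding zero counts, bins reaching L∞ (undefined age)
and, when a maximum age is supplied, bins whose midpoint age exceeds 0.95
× t_max — near the asymptote small length errors translate into huge age
errors. On geometric bin counts the estimator is exact to machine
precision; composed with the population generator at Z = 0.42 and
n = 5,000 its mean bias across 200 seeds is under 0.02 (slightly
negative, from length-at-age noise flattening the converted age
structure).

**Natural mortality.** Three life-history-invariant estimators:
longevity (M = 4.899·t_max^−0.916), growth (M = 4.118·K^0.73·L∞^−0.33,
L∞ in cm; inputs that look like mm are converted with a logged note), and
reproductive investment (M = 1.79·GSI). Each is strictly monotone in its
inputs, a property the suite asserts. Fishing mortality is F = Z − M; a
negative F is returned flagged rather than clipped, since it signals an
inconsistent M/Z pair.

**Harvest and effort.** F_MSY = 0.87·M; stock biomass is areal density ×
habitat area (km² accepted with explicit conversion); MSY =
(1 − e^(−F_MSY))·B, which keeps MSY strictly below biomass. Effort
scenarios convert MSY to net-nights (MSY / catch-per-night), fishers
(nights / nights-per-fisher-year), percent of resident families
(100 × fishers / families) and nights-per-family. Families are carried at
full precision (population / household size = 1511.1 under the default
inputs), not pre-rounded. Every chained value is kept at full precision;
rounding to display precision (rates 2 dp, yield and nights whole,
fishers and percent 1 dp, round-half-up) happens only in the reporting
twin. Default inputs describe the study fishery: Z = 0.42/yr, 4.4 kg/ha
over 276,000 ha (B = 1,214,400 kg), 15 kg per night on 50 m of
optimal-mesh net, 100 nights per fisher-year, 5,440 residents in
households of 3.6.

The spawning-run calculator sums days × daily removals over reported
periods and returns a (low, high) envelope plus a chosen point (low, mid
or high); when reported rates are ranges, the envelope is the honest
summary and no single headline number is hard-coded.

## Synthetic data

The generators emulate the study conditions the analyses assume, not any
particular lake:

- **Population**: ages with density ∝ e^(−Z·a) truncated to
  [recruit age, t_max]; VB mean length times mean-one lognormal noise
  (CV 0.10 default, a typical salmonid length-at-age spread). Recruit age
  2 yr reflects gear selection against the youngest fish.
- **Survey**: 7 sites × 4 years × 2 nets, five 4-m panels of
  2.54/3.81/5.08/6.35/7.62 cm bar mesh, one night per set. Per-set
  encounters are Poisson (negative-binomial optional via a gamma-Poisson
  mixture) with log-mean intercept + slope·(year − first year) + a
  site-level normal random intercept (SD 0.2). The default intercept
  log 15 gives ~15 fish per set, a realistic catch for a small-bodied
  dominant species on a 20-m net. Each fish draws a lognormal length and
  is allocated to a panel with probability proportional to a lognormal
  selectivity curve peaking at 100 mm of fish length per cm of bar mesh
  (putting the smallest mesh's peak at the dominant species' ~250 mm
  modal length); weights are exactly a·L^b from the recorded
  (mm-rounded) length unless weight noise is switched on.
- **Debris**: Poisson counts per transect (density × km, default 4.0
  items/km, the order the shoreline census pools to), multinomial
  categories, lognormal weights, and a mesh mixture concentrated at
  3–4 cm for net material.

Default life history for the focal grayling-like species: L∞ = 40 cm,
K = 0.13/yr, t0 = 0, t_max = 17 yr, GSI = 0.168 — chosen so the three M
estimators return values in the 0.27–0.37/yr band the assessment chain
exercises.

What the generators do **not** emulate: spatial structure within the
lake, movement, recruitment variability or multi-year feedback from
fishing, overdispersion beyond the NB option, gear saturation, and
species interactions. Passing tests therefore demonstrate the estimators'
correctness and calibration under the stated sampling model, not
robustness to every feature of real survey data.

## Numerical choices

- Seeds are explicit everywhere; fixing the seed fixes every emitted
  table byte for byte.
- The mixed-model fit retries lbfgs → cg → powell and raises with
  context if all fail; a response with zero variance short-circuits to
  slope 0, LR 0, p 1.
- A constant year column, < 2 distinct years, < 3 weighted records for
  allometry, < 3 usable trailing-arm bins, or a single mesh size raise
  informative errors rather than degenerate fits.
- Round-half-up (via `decimal`) is used for display so printed cells
  match conventional table formatting; Python's banker's rounding would
  flip some cells ending in 5.
- Problem sizes in the test and acceptance runs (200-seed Z recovery at
  n = 5,000; 1,000-replicate type-I calibration; 200-replicate power and
  recovery checks; 100–300 replicates in the acceptance script) are the
  package's chosen simulation scales: large enough that Monte Carlo error
  is small against every tolerance asserted.

## Known limitations

- The catch curve assumes equilibrium age structure and full selection on
  the trailing arm; its Z is biased by strong recruitment pulses.
- F = Z − M inherits the full uncertainty of both terms; no uncertainty
  propagation is performed (the ±0.9 kg/ha biomass uncertainty is a
  documented extension point, not implemented).
- The F_MSY = 0.87·M proxy and the three M invariants are empirical
  meta-analytic relationships; they locate the plausible range of
  sustainable harvest, they do not replace an age-structured assessment.
- The trend model is linear with site random intercepts only; random
  slopes and zero-inflated responses are out of scope.
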