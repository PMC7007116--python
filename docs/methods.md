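# Methods

## Scope and assumptions

The pipeline models the change in *dietary iron supply* — food available to be
eaten, not measured intake and not absorbed iron.  Bioavailability (heme vs
nonheme fractions, ferritin status, absorption enhancers and inhibitors) is
deliberately out of scope: animal/vegetal origin is carried as a label only.
Diets are held constant under the CO₂ scenario; no substitution behaviour is
modelled, on the reasoning that a decline in iron *content* of familiar foods
is imperceptible to consumers.

All stages operate on seven CSV tables (schemas in
`ferroclim.food_data_io`).  Countries are opaque string keys; the two study
strata are children aged 1–5 (`BOTH_1_5`) and women of childbearing age
(`F_15_49`).

## Disaggregation

For food *f* and stratum *g* in country *c*:

* if *f* has a dietary-database food group with a factor row
  (*c*, group, *g*): `supply = national × factor`;
* otherwise: `supply = national × E_g / E_national`, where `E_g` is the
  stratum's dietary energy requirement and `E_national` the national calorie
  supply.

A food whose group has no factor row for that country/stratum also takes the
energy route: partial factor coverage degrades gracefully instead of
erroring.  Factors enter here as point values; their stated uncertainty is
consumed only by the Monte Carlo stage.  Group diets are *not* renormalised
to the stratum's energy total afterwards — the scaling is per food.

## CO₂ effects

Effect rows come at two levels.  Crop-level rows always win for their food;
foods in an affected category (C₃ grains, legumes, maize) without a crop row
take the category row.  Category rows can also be derived from crop rows by
`pool_category`: means, interval bounds and p-values are sample-count-weighted
averages, counts add.  (The pooled p-value has no exact sampling
interpretation; it is a bookkeeping summary kept on the same weighting as the
mean, and the zero-effect rule is normally applied at crop level before
pooling.)

**Zero-effect rule.**  Any effect with `p > alpha` (default 0.05) is replaced
by a point mass at exactly 0 — this is how the non-significant sorghum
(p = 0.153) and potato (p = 0.555) estimates are handled.  Animal foods and
other vegetal foods without an estimate are exact zeros as well.

**Skew-normal fitting.**  Each surviving effect is represented by a
skew-normal law (location ξ, scale ω > 0, shape α; α = 0 recovers the
normal).  The three parameters are chosen so the law's median and 2.5%/97.5%
quantiles equal the reported central value and interval bounds — the minimal
well-posed reading of "a distribution based on the uncertainty interval".
Numerically the system is solved on CDF residuals at the three points
(Owen's-T evaluation is cheap and smooth) with hybrid-Powell root-finding,
the scale log-parametrised, initialised at the symmetric-normal solution and,
if needed, restarted from shapes ±1, ±3, ±8.  A fit is accepted only when the
re-evaluated *quantiles* reproduce the inputs to 1e-9 (percent units).

A skew-normal can place its median only within ≈(29.1%, 70.9%) of its own
95% interval (the half-normal limits); intervals more lopsided than that are
rejected with a `FitError` reporting the residual, rather than silently
fitted to something else.

## Monte Carlo propagation

Default 1000 iterations.  Per iteration:

* one percent-change draw per *effect entry*, shared by every country and by
  every food resolved to that entry (the effect is a property of crop
  biology, not geography; category draws are shared by member foods);
* one intake-perturbation draw per dietary-database factor, applied as a
  mean-one log-normal multiplier `exp(σZ − σ²/2)` with σ = factor_sd/factor
  (the stated SD read as a coefficient of variation), shared by the foods in
  that factor's group.

The iteration's loss for a country/stratum is the iron-weighted average
`loss% = −Σ iron_f Δ_f / Σ iron_f`, which makes every draw a convex
combination of per-food losses — a property the test suite checks draw by
draw.  Effect and intake draws are coupled within an iteration; a switch to
independent per-food effect sampling was considered and rejected as it would
understate between-country correlation of the exposure.  All randomness flows
from one `numpy` Generator per simulation, seeded explicitly: identical seeds
give bit-identical loss distributions.

## Risk classification

Median loss is banded at the fixed cutoffs 3.1%/3.8% and crossed with a 20%
anemia threshold: HIGH (loss > 3.8 and anemia > 20), MODERATE (middle band,
anemia > 20), MILD (middle band, anemia ≤ 20), NONE (loss < 3.1 regardless of
anemia).  Conventions: both cutoffs belong to the middle band; anemia exactly
20% is not "over" the threshold.  The cell the published rules leave unstated
(loss > 3.8, anemia ≤ 20) defaults to MILD and is configurable.  With
`tertile_mode=RECOMPUTE`, one cutoff pair is taken as the 33.33%/66.67%
quantiles of the pooled per-(country, stratum) medians — one pair for all
strata, mirroring the single national cutoff pair of the fixed mode.

Population aggregation sums headcounts per category and reports shares per
stratum and combined.  The top-lost-sources table sums, over HIGH-classified
(country, stratum) pairs, per-capita iron × expected loss fraction
(−E[Δ_f]/100, from the skew-normal mean) × headcount, in kg/day; both study
strata are summed, which is this package's reading of "all populations in the
highest-risk countries".

## Vegetarian scenario and diversity

The vegetarian counterfactual operates on national-average diets: animal
supplies are set to zero and every vegetal supply is multiplied by the single
factor `total_energy / vegetal_energy`, so energy is conserved exactly by
construction.  Baseline and scenario losses are simulated with the same seed
and draw count; their median difference is the incremental loss.

The diversity statistic sorts foods by iron contribution (ties broken by
food id) and counts the minimal prefix reaching 99% of total iron, excluding
trace contributors.  The association with anemia is an OLS fit of the count
on log(anemia) (natural log; `log_counts=True` exposes the alternative
log-count-on-anemia reading).  The per-country wild-harvest flag is derived
from the diet itself — wild-flagged foods contributing > 5% of national
dietary energy — since the external region list the flag would otherwise come
from is out of scope.

## Synthetic worlds

`generate_world` builds all seven tables from a `WorldConfig`.  Design
choices, in the package's own judgment of what is realistic for this domain:

* **Supplies** are constructed from calorie shares: one staple (rice) takes
  `staple_share` (default 0.4) of calories, the remainder is split by
  log-normal weights; grams follow from energy densities, so the recomputed
  national calorie supply equals the recorded one to float precision.
* **Anemia** is uniform over `anemia_range` (default 5–60%) with per-stratum
  jitter; a country's *concentration* rises with its anemia
  (`diversity_anemia_slope` scales the coupling), fattening the log-normal
  tail, boosting the staple's share and damping animal foods — which is what
  makes the negative diversity-anemia slope and the affected-share geography
  recoverable downstream.
* **CO₂ effects**: crop rows for wheat, rice, maize and field peas plus
  category rows for the three affected categories, central changes uniform in
  [−10%, −3%] with asymmetric intervals safely inside the skew-normal's
  attainable median range; sorghum and potato get fixed non-significant rows.
* **Intake factors** are log-normal around 1 (clipped to [0.75, 1.35]) with
  absolute SDs uniform in [0.02, 0.15]; national calories uniform in
  2100–2700 kcal; children's energy requirements 52–60% and women's 90–100%
  of the national supply; populations log-normal with women ≈ 2–3.5× the
  child stratum.
* **Determinism**: one RNG stream per table, derived from the master seed by
  fixed offsets, so adding a table never perturbs the others; identical
  configs give byte-identical CSVs.

What the worlds do *not* emulate: real country diet compositions, regional
nutrient-table variation (one iron density per food), within-stratum age
gradients, seasonality, or any correlation structure between countries'
diets.  Tests passing on synthetic worlds therefore demonstrate the
*machinery* — accounting identities, propagation, classification — not the
published global headline numbers, which depend on the real supply, intake
and anemia datasets.

The worked-example fixture (`cameroon_fixture`) encodes the published
single-country chain exactly: pumpkin 23.8 g/d with factor 0.958, cassava
216.8 g/d on the energy route, national supply 2175 kcal and the women's
requirement set to exactly 1.009 × 2175 — the +0.9% factor the published
arithmetic uses, rather than the rounded 2200 kcal figure, whose raw ratio
(≈ +1.15%) would not reproduce the printed 218.8 g/d.  Its anemia and
population values are plausible placeholders that only exercise downstream
stages.

## Numerical conventions and sizes

* Losses are positive percentages; per-food changes Δ are signed percentages
  (negative = loss).
* Skew-normal fit tolerance 1e-9 on quantile residuals; share normalisation
  checked to 1e-9; vegetarian energy conservation to 1e-6 relative.
* Default problem sizes in the test suite — worlds of 6–20 countries, 12–30
  foods, 30–1000 draws, with one 100,000-draw convergence check on a 5-food
  diet — were chosen as the smallest sizes at which every statistical
  property under test is comfortably resolved.

## Known limitations

* No bioavailability modelling; supply, not intake or status.
* One iron density per food; no regional composition tables.
* The pooled category p-value is a weighted bookkeeping summary, not a
  combined test.
* The diversity-anemia fit is descriptive OLS; no measurement-error model for
  either axis.
* Country keys are free text; no ISO normalisation or harmonisation with
  external country lists.
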