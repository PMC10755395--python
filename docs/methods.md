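# Methods

`basketintake` implements a validation workflow for supermarket
loyalty-card transaction records as a dietary assessment instrument:
purchased nutrients are estimated from electronic point-of-sale (EPOS)
lines, converted to individual-level daily estimates, and compared with
self-reported daily intake (an FFQ-style instrument) using Bland–Altman
agreement statistics on the log scale. Because real retailer extracts
and FFQ service outputs are confidential, the package ships a synthetic
generator with a known ground-truth agreement structure; every
downstream stage is exercised against that truth.

## Purchased-nutrient estimation

Each transaction line (customer, transaction, date, product, quantity,
cost) is linked to a per-100 g/ml back-of-pack profile for six
analytes: energy (kcal), total sugars (g), protein (g), total fat (g),
saturated fat (g) and sodium (mg). Volumes are converted with the
1 ml = 1 g approximation — no specific-gravity table is applied.
Products without a usable profile (absent, or blank/all-zero label
data) fall back to a generic per-category profile, one per each of the
15 food categories, so the post-imputation match rate is 100 % by
construction. Real studies impute at finer granularity (closest
matching generic food); one profile per category is used here because
it is reproducible and the agreement analysis depends only on totals.
Items priced by weight are modelled through `pack_amount` (e.g. a
1000 g "pack" purchased in fractional quantities) so a single formula
covers all lines.

Totals over a participant's **primary comparison period** — the ~3
months covered by their intake recall, a closed date interval with an
inclusive day count — are divided by the day count to give mean daily
household estimates. Inclusive endpoints are a fixed convention; any
choice is defensible but it must be deterministic for bit-exact
estimates.

## Household-to-individual allocation

Household purchases are attributed to the participant in proportion to
UK recommended daily energy intakes by age and gender. Other household
members' genders are not collected, so they receive the female/male
mean for their age band. The shipped recommendation table
(`data/energy_recommendations.csv`, schema `age_min, age_max,
female_kcal, male_kcal`) uses UK SACN-style age bands and reproduces
the three checkable anchors of the published method — female at 30 =
1928 kcal, female/male mean at 30 = 2230 kcal, mean at 3 = 1197.5 kcal
(forcing male at 30 = 2532) — but the full official table is not
reproducible from public text, so the table is a documented config
input. Ages are taken as recorded on the participant file (one value
per participant per run); shares are computed once per comparison
period.

One share multiplies all six analytes. Consequences tested as
invariants: shares over a household sum to 1 and individualized
vectors sum back to the household vector; and all relative
(energy-adjusted) measures are identical at household and individual
level.

## Energy-adjusted (relative) measures

Macronutrients are expressed as percentages of total energy using
protein 4, fat 9, saturated fat 9 and sugars 3.9 kcal/g (the published
method's factors, kept verbatim — including the unconventional 3.9 for
sugars); sodium is expressed in mg per kcal. The denominator is always
the estimated/reported energy field, never re-derived from
macronutrient grams, and percentages are not renormalised to sum to
100 (alcohol and other energy sources are unmodelled). Zero energy
makes the profile undefined and raises an error rather than returning
zeros; the bulk (DataFrame) API flags such rows as NaN so the
exclusion funnel can count them.

## Exclusion funnel, sensitivity filter, eligibility screen

Analysis-set rules, applied in the reported order with an auditable
ledger: no completed FFQ → no purchase in the comparison period → FFQ
daily energy ≥ 8000 kcal (outlier, boundary inclusive). The
sensitivity filter removes participants purchasing **less than**
500 kcal/d (strict; exactly 500 is retained); it defaults to
household-level purchased energy with a switch for the allocated
individual level, since the published description ("customers
purchasing less than 500 kcal/d") does not pin the level down.

The recruitment eligibility screen (≥ 7 of 15 food categories on ≥ 10
occasions in a reference year; annual spend within
[lower-quantile bound, Q3 + 1.5·IQR] of an external published spend
distribution) is implemented as a standalone predicate. The spend rule
needs reference quartiles that are external data, so it defaults to
off in synthetic runs; the lower-tail exclusion is configured as a
bound value because only its proportion, not its value, is published.

Subgroups: household size 1 / 2 / 3+; loyalty bands 0–60 %
(low-medium), 61–80 % (high), 81–100 % (very high).

## Agreement statistics

`ClassicBlandAltman` gives the mean difference (purchase − intake) and
LoA at ±1.96 sd of the differences (sample sd, n−1).

`LogRatioAgreement` is the regression approach used for the headline
analyses. Both measures are log-transformed (the spread and direction
of differences depend on the magnitude of the mean), and the
difference d = ln P − ln I is regressed on the mean
m = (ln P + ln I)/2 by unweighted OLS. LoA are drawn at ±1.96 s around
the fitted line, with s the residual sd on the n−2 denominator (the
published method does not state a denominator; n−2 is the regression
convention). The residual spread is treated as constant in m; a
magnitude-dependent residual model is out of scope. Back-transforming
gives the purchase:intake ratio at a magnitude A: ln A is plugged into
the fitted line — note this substitutes a log of a typical magnitude
for the mean-of-logs regressor, following the published recipe exactly
— and multiplicative LoA are ratio·exp(∓1.96 s). 1.96 is literal, not
a t-quantile. Pairs with a non-positive value on either side are
excluded from log analyses and counted (`excluded_nonpositive_`).
A* = exp(−β0/β1) is the magnitude at which the fitted ratio is 1,
undefined (reported absent) when β1 = 0.

Prediction magnitudes in tables: energy measures at A = 2000 kcal (the
standard reporting point, ln 2000 ≈ 7.6); other measures default to
the geometric mean of their realized mean-of-measures, since no
canonical A exists for them; both are overridable.

Estimators follow the scikit-learn protocol (`fit`, `predict`,
`get_params`, trailing-underscore fitted attributes) and the
module-level functions (`classic_ba`, `log_ba_regression`,
`predict_ratio`, `pearson_r`) are thin wrappers returning frozen
dataclasses.

## Synthetic world

The generator emulates: four recruitment waves plus a pilot, each a
study year preceded by a baseline year with a 91-day comparison window
at the wave start; a catalogue whose profile missingness is exact
(`round(rate × size)` products unmatched, 28 % by default, mirroring a
72 % pre-imputation match rate); households of size 1–5 with
non-participant members' genders unknown; five loyalty bands; and a
heteroskedastic log-scale purchase:intake structure.

**Agreement structure.** Per participant, the mean-of-logs
m ~ N(ln 2000, 0.25²) is drawn exogenously, ε ~ N(0, σ²)
independently, and d = b0 + b1·m + ε. The observed pair is
P = exp(m + d/2), I = exp(m − d/2). Drawing m first (rather than
fixing intake and solving for the purchase) is deliberate: it makes m
independent of ε, so downstream OLS of d on m is a consistent
estimator of (b0, b1) and parameter-recovery tests are meaningful. If
intake were fixed first, the realized mean would be correlated with
the noise and the OLS estimand would differ substantially from the
generating slope. Defaults b0 = 1.75, b1 = −0.25, σ = 0.70 were chosen
once so the default world reproduces the published individual-level
energy summary at A = 2000 kcal (ratio ≈ 0.86, LoA ≈ 0.22–3.43).

**Waste and under-reporting.** The imposed structure links the two
*observed* quantities (what the analysis compares). Food waste
(default 10 %, the usual population estimate) and FFQ under-reporting
(default 10 %, of similar size) therefore live in the ground-truth
bookkeeping: true intake = FFQ / (1 − underreport); the true
retailer-sourced share is clip(P·(1 − waste) / true intake, 0, 1).
They do not shift the observed purchase:FFQ relationship — the two
biases act on the unobserved truth on opposite sides and are part of
what (b0, b1, σ) summarize in a real study.

**Basket inversion.** The individual purchase target is divided by the
participant's allocation share (computed with the same allocation code
the pipeline uses) and multiplied by the day count to give the exact
household period total. A basket of 7 deterministic staple products
(oil, butter, cream, sugar, protein powder, table salt, cornflour —
chosen so their per-unit nutrient vectors positively span realistic
targets) plus 12 random catalogue products is solved by non-negative
least squares on the post-imputation effective profiles, so the target
is hit to machine precision *through the real resolution code*.
Quantities are spread over Poisson-distributed shopping trips inside
the window; baseline-year and remaining study-year trips are free
noise. Generic profiles for the staple categories equal the staple
profiles, so profile missingness never breaks exactness. Trip
frequency and basket size are placeholders (no published basket
model); only period totals matter downstream. Purchased non-energy
nutrients track the diet's per-kcal profile with per-nutrient
log-normal jitter (sd 0.15 by default), capped so macro energy stays
below 93 % of total energy (representable by real foods).

**What a green test does not establish.** The generator reproduces the
*structure* of the published world, not real shopping: no seasonality
beyond wave timing, no prices/promotions/substitution, no product-level
purchase realism, FFQ intakes emitted directly as daily nutrient
vectors (the 150-item instrument is not simulated), and the empirical
coefficient values of the real study are not reproducible without the
confidential data. Recovery tests establish that the pipeline's
statistics are consistent estimators of the generating parameters —
nothing about the real data's values.

**Determinism.** One fixed RNG stream per output family (catalogue,
cohort, transactions) derived from `SeedSequence([seed, stream])`, so
changing the cohort size leaves the catalogue untouched; identical
(seed, config) gives byte-identical CSV output.

## Numerical choices and degenerate inputs

- Closed date intervals everywhere; ISO-8601 dates.
- `round()` (banker's rounding, as documented) for the missing-profile
  count; exact by construction in tests.
- NNLS residual guard at 1e-6 relative (observed residuals are at
  machine precision); a non-representable target raises rather than
  silently degrading.
- Empty in-period purchases give a zero vector plus a flag, and are
  excluded by the funnel rather than entering log analyses.
- Groups with < 3 valid pairs are skipped with a logged warning, not
  an error; singular designs (no spread in m) raise.
- The identity ("perfect agreement") configuration uses single-person
  households: with multi-person households the household-level ratio
  is 1/share ≠ 1 by design, so only the individual level can be the
  identity there.

## Known limitations

- Allocation is energy-proportional for all nutrients (the published
  method's choice and its acknowledged error source); nutrient-specific
  allocation is a non-goal.
- Confidence intervals on the LoA, repeated-measures designs and
  mixed-effects agreement models are not implemented.
- The eligibility screen's spend reference must be supplied by the
  user; no national spend distribution is bundled.
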