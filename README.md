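# basketintake

Can supermarket loyalty-card transaction records stand in for
self-reported dietary intake? `basketintake` is a tested, reusable
pipeline for answering that question: it estimates purchased nutrients
(energy, sugars, protein, fat, saturated fat, sodium) from electronic
point-of-sale transaction lines, converts household purchases to
individual-level daily estimates by allocating them in proportion to
age/gender recommended energy intakes, and quantifies agreement with
FFQ-style self-reported intake using Bland–Altman statistics — both
for absolute daily amounts and for energy-adjusted (relative)
composition. It is aimed at nutritional epidemiologists and public
health data scientists validating or applying retailer purchase data
in dietary research.

Because real retailer and FFQ data are confidential, the package
includes a synthetic-data generator with a known ground-truth
agreement structure, so the entire pipeline is testable end to end
without any external data.

## The statistics at the core

For a purchase estimate *P* and an intake estimate *I* of the same
measure, differences are heteroskedastic — their spread and direction
depend on the magnitude of the mean — so both values are
log-transformed and the regression approach to limits of agreement is
used:

- d = ln P − ln I is regressed on m = (ln P + ln I)/2 by OLS:
  d̂ = β₀ + β₁ m
- limits of agreement: d̂ ± 1.96 s, with s the residual SD (n−2)
- at a chosen magnitude A, the purchase:intake **ratio** is
  exp(β₀ + β₁ ln A), with multiplicative LoA exp(β₀ + β₁ ln A ∓ 1.96 s)
- A\* = exp(−β₀/β₁) is the magnitude where the fitted ratio equals 1.

Individual-level purchase estimates are obtained from household
estimates via the allocation share
w(participant) / Σ members w(member), where w is the recommended daily
energy intake for the member's age (and gender where known; unknown
genders get the female/male mean). Energy-adjusted measures use
protein 4, fat 9, saturated fat 9, sugars 3.9 kcal/g and sodium in
mg/kcal; they are invariant to the allocation share.

## Worked example

```python
from basketintake import (GeneratorConfig, HouseholdMember, allocation_share)
from basketintake.pipeline import RunConfig, run

# the allocation rule on the canonical worked household:
share = allocation_share(HouseholdMember(30, "female"),
                         [HouseholdMember(30, "unknown"), HouseholdMember(3, "unknown")])
print(f"allocation share: {share:.4f}")

# a self-contained synthetic run:
config = RunConfig(generator=GeneratorConfig(seed=42, n_participants=300))
report = run(config)
print(f"analysis n = {report.ledger.final_n} (excluded {report.ledger.total_excluded})")
print(f"pre-imputation match rate = {report.match_rates[0]:.1%}")
row = report.agreement_pooled.set_index("measure").loc["individual:energy_kcal"]
print(f"individual energy: beta0={row.beta0:.3f}, beta1={row.beta1:.3f}, s={row.resid_sd:.3f}")
print(f"ratio at A=2000 kcal: {row.ratio_at_A:.2f}  LoA ({row.loa_lo_at_A:.2f}, {row.loa_hi_at_A:.2f})")
```

prints

```
allocation share: 0.3600
analysis n = 300 (excluded 0)
pre-imputation match rate = 71.7%
individual energy: beta0=3.785, beta1=-0.522, s=0.718
ratio at A=2000 kcal: 0.84  LoA (0.20, 3.41)
```

Reading the output: a 30-year-old woman living with a 30-year-old
partner of unknown gender and a 3-year-old child is allocated 36 % of
household purchased nutrients (1928/(1928 + 2230 + 1197.5) from the
recommendation table). In the synthetic cohort, 71.7 % of purchased
products carried retailer label data before generic imputation (100 %
after). At a mean magnitude of 2000 kcal/d, individual-level purchased
energy underestimates intake by about 16 % on average, but the limits
of agreement say a given participant's purchases may be anywhere from
a fifth of to 3.4 times their reported intake — wide, exactly the
behaviour the default synthetic world is configured to produce.

The same run also emits household-level and relative-measure fits (17
pooled measures), classic Bland–Altman tables, descriptive statistics,
subgroup tables by household size (1/2/3+) and loyalty (0–60 %,
61–80 %, 81–100 %), a sensitivity analysis excluding participants
purchasing under 500 kcal/d, and an auditable exclusion ledger.

A command line mirrors this: `basketintake run-all --seed 42 --out report/`
(plus `simulate`, `estimate`, `analyze` subcommands).

## Acceptance script

`scripts/acceptance.py` executes the package's main computation from
scratch — a full self-contained synthetic run at the default world
(cohort of 686, four waves plus a pilot, 91-day comparison periods):
generation, product–nutrient resolution with imputation, daily
household estimation, allocation, exclusion funnel, and all agreement
tables — and writes its results file to `--out` (with the run's tables
alongside for inspection):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/basketintake/simulate.py` — synthetic world (catalogue, cohort,
  transactions, FFQ, ground truth)
- `src/basketintake/estimation.py` — line resolution, match rates,
  daily household estimates
- `src/basketintake/allocation.py` — energy-recommendation allocation
- `src/basketintake/nutrients.py` — nutrient vectors, energy-adjusted
  composition
- `src/basketintake/filters.py` — exclusion funnel, sensitivity
  filter, subgroups, eligibility screen
- `src/basketintake/agreement.py` — Bland–Altman machinery
  (scikit-learn-style estimators)
- `src/basketintake/pipeline.py`, `cli.py`, `plots.py` — orchestration,
  command line, figures
- `docs/methods.md` — models, assumptions, numerical choices,
  limitations
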