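# dairypattern

Food-pattern modeling of **dairy fat flexibility** in the USDA 2000-kcal
Healthy U.S.-Style Eating Pattern (HUSEP).

Dietary guidance recommends three daily cup-equivalents of low-fat or
fat-free dairy. This package asks the quantitative question behind that
recommendation: if one of those servings were a reduced-fat or whole-fat
dairy food instead, would the eating pattern still stay within its limits
for calories, saturated fat (< 10% of energy), and sodium (2,300 mg/day
Chronic Disease Risk Reduction level)? It is written for nutrition
scientists and dietary-guidance modelers who need the arithmetic to be
explicit, auditable, and reusable with their own food tables.

## The model

All quantities live on a fixed 34-nutrient panel. A *dairy food composite*
is a consumption-weighted average of per-cup-equivalent food profiles
`x_i` with population intake shares `w_i > 0`:

    c = Σ_i (w_i / Σ_j w_j) · x_i

(the shipped shares are 47.76% milk, 47.30% cheese, 4.93% yogurt,
normalized over their actual sum of 99.99).

Given a reference pattern with day-level total `T` carrying `s = 3`
servings of a dairy composite `c₀`, the non-dairy remainder is
`R = T − s·c₀` (every entry must be non-negative), and a substitution plan
with components `(c_k, s_k)`, `Σ s_k = s`, yields the modeled pattern

    M = R + Σ_k s_k · c_k

Models are compared as `100·(M − M₁)/M₁` per nutrient against the
updated fat-free baseline (Model 1), with |Δ| ≥ 10% and ≥ 20% flagged on
the "good source" / "excellent source" labeling scale. Day-level profiles
are scored against 2015-era Dietary Reference Intakes
(`100·amount/goal` as % RDA/AI/UL for females 19–30 and males 51+),
macronutrient % of energy uses Atwater factors 4/4/9 kcal/g, and the
saturated-fat screen is judged on the displayed integer percent (a model
displaying 10 is *at* the limit, not over it). All arithmetic is
unrounded; half-up rounding happens only at display time.

## Worked example

```python
from dairypattern import run_models, pct_of_goal, check_thresholds

models, reports = run_models()          # Models 1-3 from the shipped tables
m1 = models["Model 1"].total
print(round(m1["energy"]), round(m1["sodium"]))      # 2006 2378
print(reports["Model 2"].display("energy"))          # 2.4  (% vs Model 1)
rows = pct_of_goal(m1, "females_19_30").set_index("nutrient_id")
print(rows.loc["calcium", "pct_display"])            # 149.0  (% of RDA)
flags = check_thresholds(m1)
print(flags.saturated_fat_pct_display, flags.sodium_exceeds_cdrr)  # 8.0 True
```

Replacing all three dairy servings with the updated fat-free composite
gives a 2,006-kcal day with 2,378 mg sodium (a 591 mg increase over the
reference pattern, driven by the higher-sodium updated composite), 8% of
energy from saturated fat, and 149% of the calcium RDA for females 19–30.
Swapping one serving for the reduced-fat composite adds 49 kcal (+2.4%).

The same workflow is available from the shell:

```
dairypattern reproduce-published          # pass/fail reconstruction table
dairypattern report --out results/    # all seven models, CSV + JSON bundle
dairypattern synth --seed 7 --out foods.csv
```

The numbered scripts under `analysis/` narrate the full study:
`01_build_composites.py` → `02_model_patterns.py` → `03_evaluate_goals.py`
→ `04_reproduction_check.py`, writing their tables under `results/`.

Models 4–7 (single whole/reduced-fat milk or cheese servings) run against
clearly-labelled synthetic stand-in food profiles, since no per-cup
profiles for those foods are published; see `docs/methods.md`.

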