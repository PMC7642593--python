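# Methods

## Scope and data flow

The package reproduces a serving-substitution analysis of the USDA
2000-kcal Healthy U.S.-Style Eating Pattern (HUSEP). Its inputs are all
printed tables shipped as machine-readable fixtures under
`src/dairypattern/data/`: the per-serving dairy composite profiles, the
reference-pattern day-level column, the published model totals and
percent changes, the published goal grid, and an encoded Dietary
Reference Intake (DRI) table. The pipeline is

1. **Composite construction** — per-serving profiles as consumption-
   share-weighted averages of per-cup food records; shares are normalized
   by their actual sum (the published shares total 99.99, not 100).
2. **Remainder derivation** — non-dairy remainder `R = T − 3·c₀`; any
   negative entry aborts with the nutrient named, since it can only mean
   inconsistent inputs.
3. **Plan application** — `M = R + Σ s_k·c_k` with `Σ s_k` required to
   equal the pattern's 3 cup-equivalents/day. Serving counts are reals
   (so 2½-serving child patterns are expressible), though every shipped
   plan uses integers.
4. **Evaluation** — percent change vs the Model 1 baseline, % RDA/AI/UL
   per age–sex group, macronutrient % of energy (Atwater 4/4/9; every
   fat class at 9 kcal/g), and saturated-fat / sodium threshold screens.

## The nutrient panel

A fixed, ordered 34-entry panel (14 macronutrient rows including the
fatty-acid fractions, 9 minerals, 11 vitamins). Units are carried exactly
as the source tables print them and are never converted: vitamin D stays
in IU; selenium, vitamin B-12, and vitamin K print as "mg" although the
conventional unit is µg, and are treated as opaque panel quantities (the
DRI table stores its goals in the same as-printed units, so ratios are
unit-consistent); vitamin A is stored in µg RAE. Energy is a panel entry,
never recomputed from macronutrients. Amounts must be non-negative on
both bases (per-serving and per-day).

Dairy composite columns print only 24 of the 34 nutrients. Missing
entries are zero-filled with a logged warning. For fiber this is
substantively correct (dairy supplies essentially none). For the
fatty-acid fractions (MUFA, PUFA, linoleic, linolenic, EPA, DHA,
stearic) and for iron and copper it is a known limitation of the printed
inputs: milk fat is roughly 30% MUFA and cheese carries trace copper, so
model totals for those nine nutrients are *not* reconstructable from the
printed composites. They are therefore excluded from reproduction
comparisons (fiber is kept), while remaining fully supported in the data
model for user-supplied food tables that do carry them.

## Rounding and reproduction tolerances

Internal arithmetic is always unrounded; display rounding is half-up
(away from zero) at each nutrient's printing precision. Half-up is used
because it reproduces every checked printed cell (46.7→47, 2.44→2.4,
66.5→67), where banker's rounding would not.

The printed inputs are themselves rounded, so recomputed cells are
compared at one unit in the last printed digit **plus propagated input
rounding**. A day-level cell combines one pattern cell and six
composite-serving cells:

    tol = 1·ulp(output) + ½·ulp(pattern) + Σ servings·½·ulp(composite)

For goal-grid integers recomputed from printed day-level amounts, a half
ulp of the amount propagates to `100·½·ulp/goal` percentage points on
top of ±1 display point; this matters exactly where the goal denominator
is small relative to the printing precision (fiber at 28 g, zinc at
8 mg, thiamin/riboflavin at ~1 mg, linolenic acid at 1.1 g), where the
published grid was clearly computed from unrounded totals that are not
recoverable from print. `ulp("0")` is taken as 1.0 (the literal precision
of the printed string), which makes a handful of zero-cell tolerances
loose but never tight. With these rules all 75 derivable day-level
cells, all 50 percent-change cells, and all 186 goal-grid cells for the
three composite models reproduce; the headline cells (energies, sodium,
Model 3 calcium, the two percent changes, and the three goal
percentages) reproduce exactly with no tolerance at all.

Two printed percent-change cells ("30" for one model's vitamin A, "27"
for another's calories) are flagged as suspected typos — both are an
order of magnitude off their column neighbors and the prose states 2.7%
for the latter — stored verbatim, and excluded from comparisons.

## The DRI table

The publication prints goal percentages but not the goals themselves.
The shipped table encodes the standard 2015-era DRI values for the two
sample groups (females 19–30, males 51+): e.g. calcium RDA 1000/1200 mg,
sodium UL 2300 mg, fiber AI 28 g (14 g per 1000 kcal at the 2000-kcal
level, hence identical for both groups), potassium AI 4700 mg — the
pre-2019 value, the only one consistent with the printed 76% adequacy.
Each value was back-checked as goal = amount ÷ (percent/100) from
matched printed cells. Sodium appears twice in configuration — as the
UL behind "% UL" rows and as the CDRR behind the threshold screen —
because the two framings are conceptually distinct even though both are
2300 mg here.

The saturated-fat screen follows the display-value reading: a model
whose unrounded share is 9.84% displays as 10 and is judged *at* the
limit, not exceeding. The unrounded share is also reported so users can
apply the stricter reading. Sodium exceeds the screen only strictly
above 2300 mg ("no more than" semantics).

## Synthetic data

`synth.generate_food_table` draws per-cup profiles log-normally
(σ = 0.15 by default) around per-group medians loosely calibrated to
per-cup dairy magnitudes, with fat-linked nutrients (fat classes,
cholesterol) scaled by tier multipliers (fat-free 1×, low-fat 8×,
reduced-fat 16×, whole 28× on a fat-free base of ~0.2–0.4 g) and energy
incremented at 9 kcal per gram of added fat. Consumption shares are
symmetric-Dirichlet draws (concentration 20) over one representative per
dairy group, scaled to sum to 100 before normalization. Each generation
call uses a single seeded generator; identical seeds give identical
output.

The generator emulates the *structure* of a food-composition table —
positive per-cup profiles, fat tiers ordered in the fat dimension,
shares summing to ~100 — and deliberately not the covariance of real
food-composition data or real consumption distributions. Passing
property tests therefore demonstrate that the arithmetic (normalization,
convexity, conservation, determinism) is correct, not that synthetic
composites resemble any particular real food.

The four single-food profiles behind the single-serving models
(whole/reduced-fat milk and cheese) are not published per cup anywhere
in the source tables. The shipped `data/synthetic_foods.csv` provides
clearly-labelled synthetic stand-ins with realistic magnitudes so those
models run end to end; their outputs are illustrative and are never
compared against printed values (with the stand-ins, the whole-fat
cheese model displays 11% of energy from saturated fat, which is why
exact reproduction is restricted to the three composite models).

## Problem sizes and determinism

All computation is desk-scale: 34-nutrient vectors, seven models, two
groups. The randomized invariant checks use 200 composite-oracle trials
and 100 end-to-end seeded replicates; the full suite runs in a few
seconds. Reports are deterministic functions of their inputs; the JSON
bundle records unrounded values, fixture checksums (sha256, verified on
every load), and the tool version, so every printed cell is traceable.

## Known limitations

- Reproduction is bounded by the precision of the printed inputs; the
  nine unprinted-in-composites nutrients are structural blind spots.
- The analysis is theoretical pattern arithmetic: nothing else in the
  pattern is re-optimized when a serving is swapped, by design.
- No unit conversion (IU↔µg), no alcohol energy, no added-sugars
  accounting beyond reporting the 120-kcal discretionary allowance as a
  constant, no child/adolescent or pregnancy groups.
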