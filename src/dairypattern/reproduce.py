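"""Reproduction of the printed model tables from printed inputs.

Starting from the printed reference-pattern column and the printed
per-serving composites, the first three substitution models are recomputed
and compared cell by cell against the printed day-level tables and the
printed goal grid.

Tolerances are expressed in units of the last printed digit (``ulp``) and
propagate the rounding already baked into the printed inputs: a recomputed
day-level cell combines one pattern cell and six composite-serving cells,
each rounded to its own printing precision, so the allowed deviation is

    tol = 1·ulp(printed output) + ½·ulp(pattern) + Σ servings·½·ulp(composite)

For the goal grid the printed day-level amounts are the inputs, and a half
ulp of the amount propagates to 100·½·ulp/goal percentage points on top of
the ±1 integer display tolerance.  Nutrients whose dairy contribution is
not printed at all (the fatty-acid fractions, iron, copper) cannot be
reconstructed and are excluded from day-level reproduction; fiber is kept,
with the dairy contribution taken as zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import PaperFixtures, load_fixtures
from .goals import ATWATER, DriTable, default_dri
from .modeling import PatternModel, run_models, usda_reference_pattern
from .panel import default_panel, round_half_up

#: Model name ↔ fixture column for the printed-composite models.
COMPOSITE_MODELS = {"Model 1": "model1", "Model 2": "model2", "Model 3": "model3"}

#: Fixture column ↔ the Table-1 composite(s) behind each model, with servings.
_MODEL_RECIPE = {
    "model1": (("composite_a", 3.0),),
    "model2": (("composite_a", 2.0), ("composite_b", 1.0)),
    "model3": (("composite_a", 2.0), ("composite_c", 1.0)),
}

_GROUP_SUFFIX = {"females_19_30": "f", "males_51_plus": "m"}


def reproducible_nutrients(fx: PaperFixtures | None = None) -> list[str]:
    """Panel nutrients whose model totals are derivable from printed inputs:
    the composite-table nutrients plus fiber (dairy supplies none)."""
    fx = fx or load_fixtures()
    derivable = set(fx.table1.index) | {"fiber"}
    return [nid for nid in default_panel().ids if nid in derivable]


def _day_level_tolerance(fx: PaperFixtures, nutrient: str, model_col: str) -> float:
    out_ulp = float(fx.model_totals_ulp.loc[nutrient, model_col])
    tol = out_ulp + 0.5 * float(fx.usda_pattern_ulp[nutrient])
    if nutrient in fx.table1.index:
        tol += 3.0 * 0.5 * float(fx.table1_ulp.loc[nutrient, "usda_2015"])
        for column, servings in _MODEL_RECIPE[model_col]:
            tol += servings * 0.5 * float(fx.table1_ulp.loc[nutrient, column])
    return tol


def model_reproduction() -> pd.DataFrame:
    """Recompute Models 1–3 and compare each derivable day-level cell.

    Returns one row per (model, nutrient): computed, printed, tol, ok.
    """
    fx = load_fixtures()
    models, _ = run_models()
    nutrients = reproducible_nutrients(fx)
    rows = []
    for name, col in COMPOSITE_MODELS.items():
        total = models[name].total
        for nid in nutrients:
            computed = total.amount(nid)
            printed = float(fx.model_totals.loc[nid, col])
            tol = _day_level_tolerance(fx, nid, col)
            rows.append(
                {
                    "model": name,
                    "nutrient_id": nid,
                    "computed": computed,
                    "printed": printed,
                    "tol": tol,
                    "ok": abs(computed - printed) <= tol,
                }
            )
    return pd.DataFrame(rows)


def pct_change_reproduction() -> pd.DataFrame:
    """Displayed percent change (vs Model 1) against the printed cells.

    Typo-flagged printed cells are carried with ``flagged=True`` and no
    verdict.  The comparison allows one unit in the printed percent's last
    digit plus the percent shift reachable from half-ulp input rounding.
    """
    fx = load_fixtures()
    models, reports = run_models()
    base = models["Model 1"].total
    rows = []
    for name, col in COMPOSITE_MODELS.items():
        if name == "Model 1":
            continue
        rep = reports[name]
        for nid in reproducible_nutrients(fx):
            printed = float(fx.pct_change.loc[nid, col])
            flagged = fx.is_typo_flagged(f"{col}_pct", nid)
            computed_display = rep.display(nid)
            # propagate half-ulp amount rounding through the ratio
            b = base.amount(nid)
            tol = np.inf
            if b > 0:
                amt_tol = _day_level_tolerance(fx, nid, col)
                base_tol = _day_level_tolerance(fx, nid, "model1")
                pct = rep.pct(nid)
                tol = 0.1 + 100.0 * amt_tol / b + abs(pct) * base_tol / b
            rows.append(
                {
                    "model": name,
                    "nutrient_id": nid,
                    "computed_display": computed_display,
                    "printed": printed,
                    "flagged": flagged,
                    "ok": None if flagged else bool(abs(computed_display - printed) <= tol),
                }
            )
    return pd.DataFrame(rows)


def table4_reproduction(
    models: tuple[str, ...] = ("model1", "model2", "model3"),
    dri: DriTable | None = None,
) -> pd.DataFrame:
    """Goal-grid reproduction from the printed day-level model columns.

    The published grid was computed from unrounded totals; recomputing from
    printed amounts can shift a percent by up to 100·½·ulp/goal, which is
    added to the ±1 integer tolerance.
    """
    fx = load_fixtures()
    dri = dri or default_dri()
    rows = []
    for _, t4row in fx.table4.reset_index().iterrows():
        nid, kind = t4row["nutrient_id"], t4row["kind"]
        for col in models:
            amount = float(fx.model_totals.loc[nid, col])
            amount_ulp = float(fx.model_totals_ulp.loc[nid, col])
            energy = float(fx.model_totals.loc["energy", col])
            energy_ulp = float(fx.model_totals_ulp.loc["energy", col])
            for group, suffix in _GROUP_SUFFIX.items():
                printed = float(t4row[f"m{col.removeprefix('model')}_{suffix}"])
                if kind == "energy_vs_goal":
                    computed = 100.0 * energy / dri.energy_goal_kcal
                    tol = 1.0 + 100.0 * 0.5 * energy_ulp / dri.energy_goal_kcal
                elif kind == "pct_kcal":
                    factor = dri.atwater.get(nid, ATWATER["fat"])
                    computed = 100.0 * amount * factor / energy
                    tol = 1.0 + (
                        100.0 * factor * 0.5 * amount_ulp + computed * 0.5 * energy_ulp
                    ) / energy
                else:  # amount_vs_goal
                    goal = dri.goal(group, nid)
                    assert goal is not None, f"no goal for {nid} / {group}"
                    computed = 100.0 * amount / goal.value
                    tol = 1.0 + 100.0 * 0.5 * amount_ulp / goal.value
                rows.append(
                    {
                        "metric": t4row["metric"],
                        "nutrient_id": nid,
                        "kind": kind,
                        "model": col,
                        "group": group,
                        "computed": computed,
                        "computed_display": round_half_up(computed, 0),
                        "printed": printed,
                        "tol": tol,
                        "ok": abs(computed - printed) <= tol,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NamedChecks:
    """The exactly-reproducible headline cells, recomputed from scratch."""

    model1_energy_kcal: float
    model1_sodium_mg: float
    sodium_increase_vs_pattern_mg: float
    model2_energy_kcal: float
    model2_sodium_mg: float
    model3_sodium_mg: float
    model3_calcium_mg: float
    model2_energy_pct_change: float
    model3_protein_pct_change: float
    model1_saturated_fat_pct_kcal_display: float
    model1_sodium_pct_ul_display: float
    model1_calcium_pct_rda_f_display: float


def named_checks() -> NamedChecks:
    from .goals import pct_kcal, pct_of_goal

    ref = usda_reference_pattern()
    models, reports = run_models(ref)
    m1, m2, m3 = (models[f"Model {i}"].total for i in (1, 2, 3))
    kcal_rows = pct_kcal(m1).set_index("nutrient_id")
    goal_rows = pct_of_goal(m1, "females_19_30").set_index("nutrient_id")
    return NamedChecks(
        model1_energy_kcal=round_half_up(m1.amount("energy"), 0),
        model1_sodium_mg=round_half_up(m1.amount("sodium"), 0),
        sodium_increase_vs_pattern_mg=round_half_up(
            m1.amount("sodium") - ref.total.amount("sodium"), 0
        ),
        model2_energy_kcal=round_half_up(m2.amount("energy"), 0),
        model2_sodium_mg=round_half_up(m2.amount("sodium"), 0),
        model3_sodium_mg=round_half_up(m3.amount("sodium"), 0),
        model3_calcium_mg=round_half_up(m3.amount("calcium"), 0),
        model2_energy_pct_change=reports["Model 2"].display("energy"),
        model3_protein_pct_change=reports["Model 3"].display("protein"),
        model1_saturated_fat_pct_kcal_display=float(
            kcal_rows.loc["saturated_fat", "pct_display"]
        ),
        model1_sodium_pct_ul_display=float(goal_rows.loc["sodium", "pct_display"]),
        model1_calcium_pct_rda_f_display=float(goal_rows.loc["calcium", "pct_display"]),
    )
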