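"""Substitution modeling: remainder derivation, plan application,
percent change, meaningful-change flags, and conservation properties."""
import numpy as np
import pytest

from dairypattern.composites import Composite, composite_from_table1
from dairypattern.modeling import (
    PlanComponent,
    PlanError,
    ReferencePattern,
    SubstitutionPlan,
    apply_plan,
    derive_remainder,
    flag_meaningful_changes,
    percent_change,
    run_models,
    shipped_plans,
    usda_reference_pattern,
)
from dairypattern.panel import NegativeAmountError, NutrientProfile, profile_scale
from dairypattern.synth import synthetic_standin_foods


class TestDeriveRemainder:
    def test_non_dairy_sodium_energy_vitamin_k(self, reference):
        remainder = derive_remainder(reference)
        assert remainder["sodium"] == pytest.approx(1787 - 3 * 202)      # 1181
        assert remainder["energy"] == pytest.approx(2003 - 3 * 77)       # 1772
        assert remainder["vitamin_k"] == pytest.approx(139.0)            # 139 - 3*0

    def test_negative_remainder_is_an_error_naming_the_nutrient(self, panel, reference):
        tiny = NutrientProfile(panel, {"calcium": 100.0}, "per_day", fill_missing=0.0)
        broken = ReferencePattern(
            name="broken",
            total=tiny,
            dairy_component=reference.dairy_component,
            dairy_servings=3.0,
        )
        with pytest.raises(NegativeAmountError, match="energy|calcium"):
            derive_remainder(broken)


class TestApplyPlan:
    def test_model_energies_match_published_results(self, composite_models):
        models, _ = composite_models
        assert round(models["Model 1"].total["energy"]) == 2006
        assert round(models["Model 2"].total["energy"]) == 2055

    def test_model3_calcium(self, composite_models):
        models, _ = composite_models
        assert round(models["Model 3"].total["calcium"]) == 1624

    def test_servings_sum_must_match_reference(self, reference):
        remainder = derive_remainder(reference)
        bad = SubstitutionPlan(
            "short", (PlanComponent(composite_from_table1("A"), 2.0),)
        )
        with pytest.raises(PlanError, match="servings"):
            apply_plan(remainder, bad, reference.dairy_servings)

    def test_total_minus_remainder_equals_serving_weighted_sum_exactly(
        self, composite_models, panel
    ):
        models, _ = composite_models
        for model in models.values():
            contributed = model.total.values - model.remainder.values
            expected = sum(
                c.servings * c.per_serving.values for c in model.plan.components
            )
            assert np.allclose(contributed, expected, rtol=0, atol=1e-9)

    def test_substituting_reference_composite_back_reproduces_pattern(self, reference):
        remainder = derive_remainder(reference)
        plan = SubstitutionPlan(
            "identity", (PlanComponent(composite_from_table1("USDA2015"), 3.0),)
        )
        model = apply_plan(remainder, plan, reference.dairy_servings)
        assert model.total.allclose(reference.total, rtol=1e-12, atol=1e-9)

    def test_monotonicity_dominating_component_never_decreases_totals(
        self, panel, reference
    ):
        remainder = derive_remainder(reference)
        a = composite_from_table1("A")
        bigger = Composite(
            name="A+",
            spec=None,
            per_serving=NutrientProfile(
                panel, a.per_serving.values + 1.0, "per_serving"
            ),
        )
        base = apply_plan(
            remainder,
            SubstitutionPlan("b", (PlanComponent(a, 2.0), PlanComponent(a, 1.0))),
            3.0,
        )
        raised = apply_plan(
            remainder,
            SubstitutionPlan("r", (PlanComponent(a, 2.0), PlanComponent(bigger, 1.0))),
            3.0,
        )
        assert np.all(raised.total.values >= base.total.values - 1e-12)


class TestPercentChange:
    def test_model2_energy_and_model3_protein_vs_model1(self, composite_models):
        _, reports = composite_models
        assert reports["Model 2"].display("energy") == 2.4
        assert reports["Model 3"].display("protein") == -1.9

    def test_model_vs_itself_is_zero_everywhere(self, composite_models):
        models, _ = composite_models
        rep = percent_change(models["Model 1"], models["Model 1"])
        assert np.all(rep.frame["pct_change"].to_numpy() == 0.0)

    def test_zero_baseline_is_flagged_not_computed(self, panel, reference):
        remainder = derive_remainder(reference)
        zeroed = NutrientProfile(
            panel,
            np.where(
                np.arange(len(panel)) == panel.index("epa"),
                0.0,
                remainder.values,
            ),
            "per_day",
        )
        a = composite_from_table1("A")
        plan = SubstitutionPlan("p", (PlanComponent(a, 3.0),))
        base = apply_plan(zeroed, plan, 3.0)
        model = apply_plan(zeroed, plan, 3.0)
        rep = percent_change(model, base)
        row = rep.frame.set_index("nutrient_id").loc["epa"]
        assert bool(row["baseline_zero"]) is True
        assert np.isnan(row["pct_change"])


class TestMeaningfulChangeFlags:
    def test_good_and_excellent_source_tiers(self, composite_models):
        _, reports = composite_models
        flags2 = dict(flag_meaningful_changes(reports["Model 2"]))
        # vitamin D rises ~19% in Model 2 -> good-source scale
        assert flags2["vitamin_d"] == "good-source-scale"
        # saturated fat rises ~22% -> excellent-source scale
        assert flags2["saturated_fat"] == "excellent-source-scale"
        assert "energy" not in flags2  # +2.4% is below any tier

    def test_zero_change_not_flagged(self, composite_models):
        models, _ = composite_models
        rep = percent_change(models["Model 1"], models["Model 1"])
        assert flag_meaningful_changes(rep) == []


class TestShippedPlans:
    def test_composites_only_plans_are_models_1_to_3(self):
        plans = shipped_plans(composites_only=True)
        assert sorted(plans) == ["Model 1", "Model 2", "Model 3"]

    def test_single_food_plans_resolve_with_standin_table(self):
        plans = shipped_plans(synthetic_standin_foods())
        assert sorted(plans) == [f"Model {i}" for i in range(1, 8)]
        for plan in plans.values():
            assert plan.total_servings == 3.0

    def test_all_seven_models_run_with_standins(self):
        models, reports = run_models(plans=shipped_plans(synthetic_standin_foods()))
        assert len(models) == 7
        # single-food models move energy up, like every substitution model
        for name, model in models.items():
            assert model.total["energy"] > 2003

    def test_unknown_baseline_rejected(self):
        with pytest.raises(PlanError, match="baseline"):
            run_models(baseline="Model 99")
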