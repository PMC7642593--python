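"""Nutrient panel structure, profile algebra, and display rounding."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dairypattern.panel import (
    ALLOWED_UNITS,
    NegativeAmountError,
    NutrientProfile,
    PanelMismatchError,
    NutrientPanel,
    PanelEntry,
    profile_add,
    profile_scale,
    profile_sub,
    round_for_display,
    round_half_up,
    zero_profile,
)


class TestPanelStructure:
    def test_panel_has_34_nutrients_energy_through_vitamin_k(self, panel):
        assert len(panel) == 34
        assert panel.ids[0] == "energy"
        assert panel.ids[-1] == "vitamin_k"
        assert "fiber" in panel

    def test_units_are_from_the_allowed_set(self, panel):
        assert {e.unit for e in panel.entries} <= ALLOWED_UNITS

    def test_categories_partition_the_panel(self, panel):
        counts = {}
        for e in panel.entries:
            counts[e.category] = counts.get(e.category, 0) + 1
        assert counts == {"macronutrient": 14, "mineral": 9, "vitamin": 11}

    def test_duplicate_ids_rejected(self):
        entry = PanelEntry("energy", "kcal", 0, "macronutrient")
        with pytest.raises(ValueError, match="unique"):
            NutrientPanel([entry, entry])


class TestProfileConstruction:
    def test_missing_nutrients_require_explicit_fill_policy(self, panel):
        with pytest.raises(KeyError, match="missing"):
            NutrientProfile(panel, {"energy": 100.0}, "per_serving")

    def test_fill_missing_warns_and_zero_fills(self, panel, caplog):
        with caplog.at_level("WARNING"):
            p = NutrientProfile(panel, {"energy": 100.0}, "per_serving", fill_missing=0.0)
        assert p["energy"] == 100.0
        assert p["fiber"] == 0.0
        assert "filling" in caplog.text

    def test_negative_amounts_rejected_with_nutrient_name(self, panel):
        amounts = np.zeros(len(panel))
        amounts[panel.index("sodium")] = -1.0
        with pytest.raises(NegativeAmountError, match="sodium"):
            NutrientProfile(panel, amounts, "per_serving")

    def test_value_semantics_input_array_not_aliased(self, panel):
        arr = np.ones(len(panel))
        p = NutrientProfile(panel, arr, "per_serving")
        arr[0] = 99.0
        assert p.values[0] == 1.0
        with pytest.raises(ValueError):
            p.values[0] = 5.0  # read-only view


class TestProfileAlgebra:
    def test_add_identity_with_zero_profile(self, panel):
        rng = np.random.default_rng(0)
        a = NutrientProfile(panel, rng.uniform(0, 50, len(panel)), "per_serving")
        assert profile_add(a, zero_profile(panel)).allclose(a)

    def test_sodium_substitution_arithmetic(self, panel):
        """1181 mg non-dairy + 3 servings at 399 mg -> 2378 mg/day."""
        remainder = NutrientProfile(panel, {"sodium": 1181.0}, "per_day", fill_missing=0.0)
        serving = NutrientProfile(panel, {"sodium": 399.0}, "per_serving", fill_missing=0.0)
        total = profile_add(remainder, profile_scale(serving, 3, basis="per_day"))
        assert total["sodium"] == pytest.approx(2378.0)

    def test_add_matches_elementwise_oracle(self, panel):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_day")
            b = NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_day")
            oracle = [a.amount(n) + b.amount(n) for n in panel.ids]  # brute force
            assert np.allclose(profile_add(a, b).values, oracle)

    def test_add_requires_matching_panel_and_names_first_difference(self, panel):
        other = NutrientPanel([PanelEntry("energy", "kcal", 0, "macronutrient")])
        a = zero_profile(panel)
        b = zero_profile(other)
        with pytest.raises(PanelMismatchError, match="protein"):
            profile_add(a, b)

    def test_add_requires_matching_basis(self, panel):
        with pytest.raises(ValueError, match="basis"):
            profile_add(zero_profile(panel, "per_day"), zero_profile(panel, "per_serving"))

    def test_scale_by_one_and_zero(self, panel):
        rng = np.random.default_rng(2)
        a = NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_serving")
        assert profile_scale(a, 1.0).allclose(a)
        assert np.all(profile_scale(a, 0.0).values == 0.0)

    def test_scale_composite_energy_by_servings(self, panel):
        a = NutrientProfile(panel, {"energy": 77.0}, "per_serving", fill_missing=0.0)
        assert profile_scale(a, 3, basis="per_day")["energy"] == pytest.approx(231.0)

    def test_negative_scale_rejected(self, panel):
        with pytest.raises(ValueError, match=">= 0"):
            profile_scale(zero_profile(panel), -0.5)

    def test_subtraction_driving_negative_names_nutrient(self, panel):
        small = NutrientProfile(panel, {"calcium": 10.0}, "per_day", fill_missing=0.0)
        big = NutrientProfile(panel, {"calcium": 20.0}, "per_day", fill_missing=0.0)
        with pytest.raises(NegativeAmountError, match="calcium"):
            profile_sub(small, big)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 10.0))
    def test_scale_distributes_over_add(self, seed, k):
        panel = __import__("dairypattern").default_panel()
        rng = np.random.default_rng(seed)
        a = NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_day")
        b = NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_day")
        left = profile_scale(profile_add(a, b), k)
        right = profile_add(profile_scale(a, k), profile_scale(b, k))
        assert left.allclose(right, rtol=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_add_commutative_and_associative(self, seed):
        panel = __import__("dairypattern").default_panel()
        rng = np.random.default_rng(seed)
        a, b, c = (
            NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_day")
            for _ in range(3)
        )
        assert profile_add(a, b).allclose(profile_add(b, a))
        assert profile_add(profile_add(a, b), c).allclose(
            profile_add(a, profile_add(b, c)), rtol=1e-9
        )


class TestDisplayRounding:
    @pytest.mark.parametrize(
        "value,ndigits,expected",
        [
            (2.44, 1, 2.4),
            (2.45, 1, 2.5),   # half-up, not banker's
            (46.7, 0, 47.0),
            (7.716, 0, 8.0),  # saturated-fat % of kcal case
            (66.5, 0, 67.0),
            (-1.85, 1, -1.9),  # half away from zero on negatives
        ],
    )
    def test_half_up_examples(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected

    def test_round_for_display_uses_panel_precisions(self, panel):
        amounts = {nid: 2.444 for nid in panel.ids}
        table = round_for_display(NutrientProfile(panel, amounts, "per_day"))
        lookup = table.set_index("nutrient_id")["value"]
        assert lookup["energy"] == 2.0        # 0 decimals
        assert lookup["saturated_fat"] == 2.4  # 1 decimal
        assert lookup["epa"] == 2.44           # 2 decimals

    def test_rounding_is_idempotent_and_never_mutates(self, panel):
        rng = np.random.default_rng(3)
        p = NutrientProfile(panel, rng.uniform(0, 100, len(panel)), "per_day")
        before = p.values.copy()
        once = round_for_display(p)
        rounded = NutrientProfile(panel, once["value"].to_numpy(), "per_day")
        twice = round_for_display(rounded)
        assert np.all(once["value"].to_numpy() == twice["value"].to_numpy())
        assert np.all(p.values == before)
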