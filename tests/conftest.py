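import numpy as np
import pytest

from dairypattern.composites import FoodRecord
from dairypattern.fixtures import load_fixtures
from dairypattern.modeling import run_models, usda_reference_pattern
from dairypattern.panel import NutrientProfile, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def fx():
    return load_fixtures()


@pytest.fixture(scope="session")
def reference():
    return usda_reference_pattern()


@pytest.fixture(scope="session")
def composite_models():
    """Models 1-3 recomputed from printed inputs, with % change vs Model 1."""
    return run_models()


def random_profile(panel, rng, basis="per_serving", scale=100.0):
    return NutrientProfile(panel, rng.uniform(0.0, scale, size=len(panel)), basis)


def make_food(panel, code, amounts_array, group="milk", tier="fat_free"):
    return FoodRecord(
        food_code=code,
        description=f"test food {code}",
        group=group,
        fat_tier=tier,
        profile=NutrientProfile(panel, amounts_array, "per_serving"),
    )
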