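import numpy as np
import pandas as pd
import pytest

import foodbudget as fb


@pytest.fixture(scope="session")
def registry():
    return fb.default_registry()


@pytest.fixture(scope="session")
def bundle():
    """Shared 3-country synthetic world (moderately unhealthy diets)."""
    return fb.generate(fb.SynthConfig(seed=1, n_countries=3, unhealthiness=0.5))


@pytest.fixture(scope="session")
def run_result(bundle):
    return fb.run_bundle(
        bundle.profiles, bundle.nutrients, bundle.constraints, bundle.registry,
        prices=bundle.prices, pli=bundle.pli, incomes=bundle.incomes,
        base_country=bundle.base_country,
    )


@pytest.fixture(scope="session")
def toy_nutrients():
    """Three-group toy nutrient table (bread / milk / water-like)."""
    frame = pd.DataFrame(
        {
            "energy_kcal": [250.0, 60.0, 0.0],
            "protein_g": [8.0, 3.3, 0.0],
            "fat_g": [1.0, 3.5, 0.0],
            "carb_g": [50.0, 4.7, 0.0],
            "fibre_g": [4.0, 0.0, 0.0],
            "water_g": [35.0, 85.0, 99.9],
            "salt_g": [1.2, 0.1, 0.0],
        },
        index=["bread", "milk", "water"],
    )
    return fb.NutrientTable(frame)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
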