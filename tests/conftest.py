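import numpy as np
import pandas as pd
import pytest

from meddiet import CutoffTable


def make_simple_cutoffs() -> CutoffTable:
    """Round-number cutoff table for hand-checkable scoring tests."""
    medians = {"vegetables": 200.0, "fruits_nuts": 150.0, "legumes": 50.0,
               "fish": 60.0, "cereals": 300.0, "meat": 80.0, "dairy": 150.0,
               "fat_ratio": 1.2}
    tertiles = {c: (m * 0.8, m * 1.25) for c, m in medians.items() if c != "fat_ratio"}
    tertiles["olive_oil"] = (1.0, 5.0)
    return CutoffTable(medians=medians, tertiles=tertiles)


@pytest.fixture
def simple_cutoffs() -> CutoffTable:
    return make_simple_cutoffs()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_intakes(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random positive component-intake table spanning the cutoff ranges."""
    cols = {}
    for comp, scale in [("vegetables", 200), ("fruits_nuts", 150), ("legumes", 50),
                        ("fish", 60), ("cereals", 300), ("meat", 80), ("dairy", 150),
                        ("olive_oil", 3), ("mufa_g", 18), ("sfa_g", 16)]:
        cols[comp] = scale * rng.lognormal(0.0, 0.6, size=n)
    cols["ethanol_g"] = np.where(rng.random(n) < 0.3,
                                 rng.uniform(0, 40, size=n), 0.0)
    df = pd.DataFrame(cols)
    df.insert(0, "participant_id", np.arange(1, n + 1))
    return df
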