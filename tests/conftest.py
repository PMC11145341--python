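import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from percept import CohortSpec, FeatureTable, generate_cohort

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic case/control cohort with known truth."""
    spec = CohortSpec(
        n_features=60, n_control=6, n_case=8, affected_fraction=0.25,
        effect_log2=1.0, noise_sd_log2=0.3, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def hand_table():
    """3-feature intensity table with hand-checkable ratios."""
    data = pd.DataFrame(
        {
            "c1": [8.0, 10.0, 4.0],
            "c2": [12.0, 10.0, 4.0],
            "c3": [10.0, 10.0, 4.0],
            "d1": [15.0, 20.0, 4.0],
            "d2": [5.0, 10.0, 8.0],
        },
        index=pd.Index(["fA", "fB", "fC"], name="feature_id"),
    )
    groups = pd.Series(
        ["control"] * 3 + ["case"] * 2, index=data.columns
    )
    return FeatureTable(data=data, groups=groups, value_space="intensity")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
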