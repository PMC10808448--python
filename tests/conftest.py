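import numpy as np
import pandas as pd
import pytest

from gutmediate.containers import FeatureTable, SampleMetadata
from gutmediate.simulate import SimulationConfig, generate_cohort, generate_truth


@pytest.fixture
def tiny_counts() -> FeatureTable:
    """2-taxon × 2-sample counts table used across format tests."""
    return FeatureTable(
        pd.DataFrame([[2, 5], [3, 0]], index=["tA", "tB"], columns=["s1", "s2"]),
        unit="counts")


@pytest.fixture
def small_meta() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "exposure": [1.0, 0.0, 1.0],
        "bmi": [18.4, 18.5, np.nan],
        "age": [70.0, 65.0, 72.0],
        "sex": [0.0, 1.0, 1.0],
    }, index=["s1", "s2", "s3"]))


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions (seeded)."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_truth():
    """Monte-Carlo ground truth at the default study conditions."""
    return generate_truth(SimulationConfig(), n_mc=200_000)
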