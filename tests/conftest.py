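import numpy as np
import pandas as pd
import pytest

from catgut.simulate import CohortSpec, default_effect_spec, generate_design
from catgut.tables import FeatureTable, StudyDesign


@pytest.fixture(scope="session")
def default_design() -> StudyDesign:
    return generate_design(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_effects():
    return default_effect_spec(seed=7)


@pytest.fixture()
def small_counts() -> FeatureTable:
    data = pd.DataFrame(
        {"s1": [2, 3, 5], "s2": [10, 0, 10]},
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"))
    return FeatureTable("genus", data, "counts")


@pytest.fixture()
def unit_cluster_design() -> StudyDesign:
    """One sample per kitten at two ages: GEE reduces to plain logistic."""
    rows = []
    for i in range(10):
        rows.append(dict(sample_id=f"a{i}", kitten_id=f"ka{i}", litter_id="L1",
                         sex="F", neuter_group="EN", age_week=18, denominator=100))
        rows.append(dict(sample_id=f"b{i}", kitten_id=f"kb{i}", litter_id="L2",
                         sex="F", neuter_group="EN", age_week=30, denominator=100))
    return StudyDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
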