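import numpy as np
import pandas as pd
import pytest

from gvhdgrading import GeneratorConfig, fit_pc1, generate_cohort
from gvhdgrading.cohort import CohortTable


def make_cohort(rows, origin="hct_day"):
    """Build a cohort from (id, skin, liver, gi, time, event, os_event) tuples."""
    df = pd.DataFrame(
        rows, columns=["id", "skin", "liver", "gi", "time_days", "event", "os_event"]
    )
    return CohortTable(df, origin=origin)


@pytest.fixture(scope="session")
def train_cohort():
    """Training-sized synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n=2319, seed=2))


@pytest.fixture(scope="session")
def test_cohort():
    """Independent test-sized synthetic cohort."""
    return generate_cohort(GeneratorConfig(n=700, seed=3))


@pytest.fixture(scope="session")
def repertoire_cohort():
    """Training cohort guaranteed to cover all 124 aGVHD phenotypes."""
    return generate_cohort(
        GeneratorConfig(n=5000, seed=1, include_full_repertoire=True)
    )


@pytest.fixture(scope="session")
def pc1_model(repertoire_cohort):
    with pytest.warns(UserWarning, match="clamped"):
        return fit_pc1(repertoire_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
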