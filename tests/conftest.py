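import numpy as np
import pandas as pd
import pytest

from gutcross.simulate import SimulationConfig, simulate_cohort
from gutcross.tables import CohortMetadata, CountTable


@pytest.fixture(scope="session")
def planted_cohort():
    """Balanced cohort with the default focal-taxon depletion (0.58 -> 0.36)."""
    cfg = SimulationConfig(n_exposed=40, n_control=40, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no exposure effect (focal_effect = 1)."""
    cfg = SimulationConfig(n_exposed=40, n_control=40, focal_effect=1.0, seed=8)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_table():
    """Small deterministic count table."""
    data = pd.DataFrame(
        [[10, 0, 3, 7], [0, 5, 2, 1], [4, 4, 0, 2]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountTable(data)


def make_metadata(n_exposed, n_control, prefix="S", covariate=None):
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_exposed + n_control)]
    frame = pd.DataFrame(
        {"exposure": [1] * n_exposed + [0] * n_control},
        index=pd.Index(ids, name="sample_id"),
    )
    if covariate is not None:
        frame["covariate"] = covariate
    return CohortMetadata(frame)
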