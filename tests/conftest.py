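import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabodisc import PeakTable, SimulationConfig, generate_dataset, inject_missingness

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def seeded_table():
    """26 × 50 censored peak table with ground truth (seed 11)."""
    cfg = SimulationConfig(n_metabolites=50, n_informative=5, missing_rate=0.1, seed=11)
    table, truth = generate_dataset(cfg)
    return inject_missingness(table, cfg), truth


@pytest.fixture()
def hand_table():
    """Tiny hand-built table: 4 samples, 3 metabolites on 2 methods."""
    values = pd.DataFrame(
        {
            "m1": [2.0, 4.0, 8.0, 16.0],
            "m2": [4.0, 8.0, 16.0, 32.0],
            "m3": [8.0, 8.0, 8.0, 8.0],
        },
        index=["L01", "L02", "H01", "H02"],
    )
    population = pd.Series(["L", "L", "H", "H"], index=values.index)
    methods = pd.Series(["A", "A", "B"], index=values.columns)
    return PeakTable(values=values, population=population, method_of=methods)


def two_group_labels(n_per_group: int) -> np.ndarray:
    return np.array(["L"] * n_per_group + ["H"] * n_per_group)
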