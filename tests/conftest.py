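import numpy as np
import pandas as pd
import pytest

from dietbiome import SimulationConfig, simulate_cohorts
from dietbiome.io_formats import AbundanceTable, FFQTable, SampleMetadata


@pytest.fixture(scope="session")
def small_sim():
    """3 modest cohorts with planted omnivore-vs-vegan effects; shared across tests."""
    cfg = SimulationConfig(
        cohort_sizes=(300, 300, 300),
        n_features=100,
        n_signature_features=6,
        planted_smd=1.0,
        seed=7,
    )
    table, metadata, ffq, truth = simulate_cohorts(cfg)
    return cfg, table, metadata, ffq, truth


@pytest.fixture()
def toy_table():
    return AbundanceTable(
        pd.DataFrame(
            [[50.0, 30.0, 20.0], [10.0, 70.0, 20.0]],
            index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture()
def toy_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "cohort": ["C1", "C1"],
                "diet": ["omnivore", "vegan"],
                "sex": ["female", "male"],
                "age": [40.0, 50.0],
                "bmi": [22.0, 27.0],
            },
            index=["s1", "s2"],
        )
    )


@pytest.fixture()
def toy_ffq():
    intakes = pd.DataFrame(
        {"milk": [1.5, 0.0], "cheese": [2.0, 0.5], "apple": [1.0, 3.0]},
        index=["s1", "s2"],
    )
    gm = pd.DataFrame(
        {
            "item": ["milk", "cheese", "apple"],
            "group": ["dairy", "dairy", "fruits"],
            "hpdi_flag": ["reverse", "reverse", "positive"],
        }
    ).set_index("item")
    return FFQTable(intakes=intakes, group_map=gm)
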