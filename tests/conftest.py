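import numpy as np
import pandas as pd
import pytest

from exparallel import CountMatrix, SampleDesign, SimulationConfig, simulate_study


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {"s1": [1, 3], "s2": [2, 4]},
            index=["g1", "g2"],
            dtype="int64",
        )
    )


@pytest.fixture
def tiny_design() -> SampleDesign:
    rows = []
    for i in range(2):
        rows.append((f"e{i + 1}", "within_population", "rep01", f"s{i + 1}", "evolved"))
    for i in range(2):
        rows.append((f"a{i + 1}", "within_population", "founder", "", "ancestral"))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "level", "lineage_id", "subreplicate_id", "state"])
    )


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_genes=300, n_sets=40, set_size_range=(5, 20), seed=7
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


def make_design_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "level", "lineage_id", "subreplicate_id", "state"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
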