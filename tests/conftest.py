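import numpy as np
import pandas as pd
import pytest

from coexmap import (ExpressionMatrix, SimulationConfig, simulate_dataset,
                     simulate_timecourse)
from coexmap.orthology import OrthogroupTable, SpeciesTree

STAGES = ["E4", "E6", "E10", "E14", "eN", "mN", "lN", "A"]


@pytest.fixture(scope="session")
def dataset():
    """Default two-species study-condition dataset (planted truth included)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def timecourse():
    """8-stage, 4-cluster developmental time course at noise 0.2."""
    return simulate_timecourse(STAGES, n_clusters=4, genes_per_cluster=50,
                               noise_sd=0.2, seed=7)


@pytest.fixture()
def toy_tree():
    return SpeciesTree("((A,B),C);")


@pytest.fixture()
def toy_table():
    return OrthogroupTable(
        {
            "OG1": {"A": ("a1",), "B": ("b1",), "C": ()},
            "OG2": {"A": ("a2", "a3"), "B": (), "C": ("c1",)},
            "OG3": {"A": ("a4",), "B": (), "C": ()},
            "OG4": {"A": ("a5",), "B": ("b2",), "C": ("c2",)},
        },
        ["A", "B", "C"],
    )


def make_matrix(values, samples=None, genes=None, unit="cRPKM"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    cond = pd.Series(samples, index=samples)
    return ExpressionMatrix(df, cond, unit=unit)
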