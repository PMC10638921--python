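import numpy as np
import pandas as pd
import pytest

from sigbench import GeneExpressionMatrix, SimulationSpec, make_count_experiment
from sigbench.synthetic import PlantedTerm


@pytest.fixture
def toy_counts() -> GeneExpressionMatrix:
    """5 genes x 8 samples of counts with simple known structure."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.poisson(50, size=(5, 8)).astype(float),
        index=[f"G{i}" for i in range(1, 6)],
        columns=[f"T{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 5)],
    )
    return GeneExpressionMatrix(values=values, value_kind="counts")


@pytest.fixture
def groups():
    return ["T1", "T2", "T3", "T4"], ["C1", "C2", "C3", "C4"]


@pytest.fixture(scope="session")
def small_count_experiment():
    """A small planted-term count experiment shared across tests."""
    spec = SimulationSpec(
        seed=7,
        n_genes=1500,
        n_decoy_terms=19,
        planted_terms={"TF001 001 ChIP-Seq SIM Human": PlantedTerm(size=40, effect=2.0)},
    )
    return make_count_experiment(spec)
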