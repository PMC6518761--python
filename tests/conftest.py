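import numpy as np
import pandas as pd
import pytest

from mirpair.datatypes import ExpressionMatrix, SampleGroups
from mirpair.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study: 500 genes, 60 miRNAs, 15+15 samples, 50 planted pairs."""
    return simulate(SimulationConfig(seed=1234))


@pytest.fixture(scope="session")
def small_bundle():
    """A fast bundle for structural tests (not sized for power-dependent checks)."""
    return simulate(
        SimulationConfig(
            n_genes=120,
            n_mirnas=20,
            n_per_group=8,
            n_planted_pairs=12,
            n_de_mirnas=6,
            n_de_genes=10,
            n_gene_sets=8,
            genes_per_set=12,
            seed=99,
        )
    )


def make_two_group(values: np.ndarray, prefix=("c", "t")) -> tuple[ExpressionMatrix, SampleGroups]:
    """Wrap a features x (n/2 + n/2) array as matrix + balanced two-group design."""
    n = values.shape[1]
    half = n // 2
    samples = [f"{prefix[0]}{i}" for i in range(half)] + [f"{prefix[1]}{i}" for i in range(n - half)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=[f"F{i}" for i in range(values.shape[0])], columns=samples)
    )
    groups = SampleGroups(
        {s: ("control" if s.startswith(prefix[0]) else "case") for s in samples}, "control"
    )
    return expr, groups
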