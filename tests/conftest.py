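import numpy as np
import pandas as pd
import pytest

from danseq.containers import CountMatrix
from danseq.network import network_attributes
from danseq.synthetic import (
    SimulationConfig,
    SyntheticNetworkConfig,
    default_nb_params,
    generate_annotations,
    generate_synthetic_network,
    simulate_counts,
)


@pytest.fixture(scope="session")
def nb_template() -> pd.DataFrame:
    return default_nb_params()


@pytest.fixture(scope="session")
def null_counts(nb_template) -> tuple[CountMatrix, pd.Series]:
    """3v3 null simulation (no condition effect), 2000 genes."""
    return simulate_counts(SimulationConfig(n_genes=2000, p_diff=0.0, seed=11), nb_template)


@pytest.fixture(scope="session")
def planted_counts(nb_template) -> tuple[CountMatrix, pd.Series]:
    """3v3 simulation with 10% of genes at fold 3, 2000 genes."""
    return simulate_counts(SimulationConfig(n_genes=2000, p_diff=0.1, seed=12), nb_template)


@pytest.fixture(scope="session")
def planted_network():
    """800-gene network with two planted modules plus attribute table."""
    G = generate_synthetic_network(
        SyntheticNetworkConfig(n_genes=800, module_sizes=(50, 40), seed=21)
    )
    terms, attrs = generate_annotations(
        list(G.nodes), G.graph["modules"], n_terms=15, overlap_fraction=0.9, seed=22
    )
    return G, network_attributes(G, attrs), terms


@pytest.fixture(scope="session")
def null_network():
    """Homogeneous network (no modules) plus attribute table."""
    G = generate_synthetic_network(
        SyntheticNetworkConfig(
            n_genes=800, module_sizes=(), within_density=0.0, background_density=0.02, seed=23
        )
    )
    _, attrs = generate_annotations(list(G.nodes), [], n_terms=5, seed=24)
    return G, network_attributes(G, attrs)


def make_count_matrix(arr, conditions, sexes=None, ages=None, genes=None):
    """Small hand-built CountMatrix for unit tests."""
    arr = np.asarray(arr)
    n = arr.shape[1]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "sex": sexes or [("M", "F")[i % 2] for i in range(n)],
            "age": ages or list(np.linspace(40, 70, n)),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples), meta)
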