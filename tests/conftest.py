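import networkx as nx
import numpy as np
import pytest

from isap import GeneSetCollection, OmicsDataset, SimulationConfig, generate_cohort
from isap.simulate import make_gene_sets, make_string_edges


@pytest.fixture(scope="session")
def small_cohort() -> OmicsDataset:
    """Default-condition cohort at reduced size, shared across read-only tests."""
    cfg = SimulationConfig(n_tissues=3, samples_per_tissue=40, n_meth_features=60,
                           n_expr_features=60, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def ppi_graph() -> nx.Graph:
    edges = make_string_edges(n_nodes=30, edge_prob=0.18, seed=7)
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["protein_a"], row["protein_b"], score=int(row["score"]))
    return g


@pytest.fixture(scope="session")
def gene_collection() -> GeneSetCollection:
    genes = [f"gene_{i:04d}" for i in range(60)]
    sets = make_gene_sets(genes, n_sets=12, set_size=8, seed=3)
    return GeneSetCollection(sets=sets, universe=genes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
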