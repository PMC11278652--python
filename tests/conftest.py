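import networkx as nx
import numpy as np
import pandas as pd
import pytest

import riverweb as rw


@pytest.fixture(scope="session")
def recovery_spec():
    """Three planted modules of 20 OTUs, strong block correlation, 60 samples."""
    return rw.CommunitySpec(
        n_otus=80,
        n_sites=30,
        module_spec=[(20, 0.95)] * 3,
        zero_inflation=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def recovery_dataset(recovery_spec):
    return rw.generate_dataset(recovery_spec)


@pytest.fixture(scope="session")
def recovery_network(recovery_dataset):
    ds = recovery_dataset
    # synthetic tables are generated on a common scale, so the per-domain
    # renormalization used for merged two-primer tables is switched off
    return rw.build_cooccurrence_network(
        ds.table, ds.taxonomy, ds.metadata, scope="both", renormalize_domains=False
    )


def make_labeled_graph(edges, phylum_of, domain_of=None, abundance=None):
    """Small helper: undirected graph with taxonomy node attributes."""
    g = nx.Graph()
    g.add_edges_from(edges)
    for n in g.nodes:
        g.nodes[n]["phylum"] = phylum_of[n]
        g.nodes[n]["domain"] = (domain_of or {}).get(n, "Bacteria")
        g.nodes[n]["mean_abundance"] = (abundance or {}).get(n, 0.01)
    return g


@pytest.fixture
def triangle_network():
    return make_labeled_graph(
        [("a", "b"), ("b", "c"), ("a", "c")],
        phylum_of={"a": "P1", "b": "P1", "c": "P2"},
        domain_of={"a": "Bacteria", "b": "Bacteria", "c": "Archaea"},
    )


@pytest.fixture
def small_otu_table():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.dirichlet(np.ones(6), size=8),
        index=[f"s{i}" for i in range(8)],
        columns=[f"OTU{i}" for i in range(6)],
    )
    return rw.OtuTable(data)
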