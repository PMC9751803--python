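import networkx as nx
import numpy as np
import pandas as pd
import pytest

from otunet import CoNetwork, OtuTable
from otunet.otu_table import RANKS, UNCLASSIFIED


def make_table(counts: np.ndarray, phyla=None, groups=None) -> OtuTable:
    """Small OtuTable from a raw count matrix (OTU x sample)."""
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    otu_ids = [f"OTU{i}" for i in range(n_otus)]
    sample_ids = [f"S{j}" for j in range(n_samples)]
    taxonomy = pd.DataFrame(UNCLASSIFIED, index=otu_ids, columns=list(RANKS))
    taxonomy["kingdom"] = "Bacteria"
    taxonomy["phylum"] = phyla if phyla is not None else "Firmicutes"
    metadata = pd.DataFrame(
        {"group": groups if groups is not None else ["G1"] * n_samples},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return OtuTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        taxonomy=taxonomy,
        metadata=metadata,
    )


def as_conetwork(g: nx.Graph, threshold: float = 0.5) -> CoNetwork:
    """Wrap a plain graph as a CoNetwork with default edge/node attributes."""
    gg = nx.Graph()
    gg.add_nodes_from(sorted(g.nodes, key=str))
    for u, v, d in g.edges(data=True):
        gg.add_edge(
            u, v, weight=d.get("weight", 0.9), sign=d.get("sign", 1)
        )
    for n in gg.nodes:
        gg.nodes[n].setdefault("phylum", "Firmicutes")
    return CoNetwork(graph=gg, threshold=threshold)


@pytest.fixture
def triangle():
    return as_conetwork(nx.cycle_graph(3))


@pytest.fixture
def path4():
    return as_conetwork(nx.path_graph(4))


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return as_conetwork(g)


@pytest.fixture
def star10():
    """Star K1,9: hub node 0, nine leaves."""
    return as_conetwork(nx.star_graph(9))


@pytest.fixture
def k10():
    return as_conetwork(nx.complete_graph(10))


#: connected graphs with <= 8 nodes used for brute-force oracle checks
SMALL_GRAPHS = [
    nx.path_graph(4),
    nx.cycle_graph(5),
    nx.star_graph(6),
    nx.complete_graph(5),
    nx.barbell_graph(3, 1),
    nx.lollipop_graph(4, 3),
    nx.wheel_graph(7),
    nx.gnp_random_graph(8, 0.4, seed=7),
    nx.gnp_random_graph(8, 0.6, seed=11),
    nx.gnp_random_graph(7, 0.5, seed=3),
]
SMALL_GRAPHS = [g for g in SMALL_GRAPHS if nx.is_connected(g)]


def write_otu_tsv(path, rows, header="#OTU ID\tS1\tS2\ttaxonomy", comments=()):
    lines = list(comments) + [header] + rows
    path.write_text("\n".join(lines) + "\n")


def write_metadata_tsv(path, samples, groups=None):
    groups = groups or ["G1"] * len(samples)
    lines = ["sample_id\tgroup\ttimepoint"] + [
        f"{s}\t{g}\tT1" for s, g in zip(samples, groups)
    ]
    path.write_text("\n".join(lines) + "\n")
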