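import numpy as np
import pytest

from consnet.trees import (
    Cluster,
    GeneTreeCollection,
    Phylogeny,
    TaxonSet,
    parse_newick,
)

FIG_TREES = [
    "((x,y)40,(z,w)100,u);",
    "((x,y)45,(z,w)100,u);",
    "((x,u)90,(z,w)100,y);",
]


@pytest.fixture(scope="session")
def fig_taxa() -> TaxonSet:
    return TaxonSet(["x", "y", "z", "w", "u"])


@pytest.fixture(scope="session")
def fig_trees(fig_taxa):
    return [parse_newick(s, taxon_set=fig_taxa) for s in FIG_TREES]


@pytest.fixture(scope="session")
def fig_collection(fig_trees):
    return GeneTreeCollection(list(fig_trees))


def random_binary_tree(n_taxa: int, rng: np.random.Generator, taxon_set=None) -> Phylogeny:
    """Independent random-topology generator for oracles (not the simulator)."""
    import itertools

    import networkx as nx

    ts = taxon_set or TaxonSet([f"s{i}" for i in range(n_taxa)])
    g = nx.Graph()
    ids = itertools.count()
    a, b, c, hub = (next(ids) for _ in range(4))
    g.add_node(hub)
    for leaf, lab in zip((a, b, c), ts.labels[:3]):
        g.add_node(leaf, taxon=lab)
        g.add_edge(hub, leaf, length=None, support=None)
    for lab in ts.labels[3:]:
        edges = list(g.edges)
        u, v = edges[rng.integers(0, len(edges))]
        g.remove_edge(u, v)
        mid, leaf = next(ids), next(ids)
        g.add_node(mid)
        g.add_node(leaf, taxon=lab)
        g.add_edge(u, mid, length=None, support=None)
        g.add_edge(mid, v, length=None, support=None)
        g.add_edge(mid, leaf, length=None, support=None)
    return Phylogeny(g, ts, rooted=False, root=hub)


def random_cluster(ts: TaxonSet, rng: np.random.Generator) -> Cluster:
    m = len(ts)
    while True:
        mask = int(rng.integers(1, ts.full_mask))
        if 2 <= mask.bit_count() <= m - 2:
            return Cluster(ts, mask)
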