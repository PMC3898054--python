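"""Consensus tree construction from weighted clusters.

Four methods are provided:

* support-based majority rule — clusters whose average support exceeds the
  cutoff (pairwise compatible by construction at cutoff >= 50);
* support-based extended majority rule — majority set first, then remaining
  clusters greedily in descending weight order while compatible;
* support-based Nelson consensus — maximum-total-weight clique(s) of the
  cluster compatibility graph; with several maximum cliques only their
  intersection is kept and the rest is reported as ambiguous;
* weight-based extended majority rule — greedy accretion over an externally
  supplied ranking (any weighting mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .trees import (
    Cluster,
    GeneTreeCollection,
    Phylogeny,
    TaxonSet,
    TreeError,
    are_compatible,
    tree_from_clusters,
)
from .weights import WeightedCluster, rank_clusters

__all__ = [
    "ConsensusResult",
    "bootstrap_majority",
    "bootstrap_extended_majority",
    "nelson_consensus",
    "weighted_extended_majority",
]

NELSON_DEFAULT_CAP = 64


@dataclass
class ConsensusResult:
    tree: Phylogeny
    included: list[WeightedCluster]
    method: str
    ambiguous: list[WeightedCluster] = field(default_factory=list)


def _build(included: list[WeightedCluster], ts: TaxonSet, method: str,
           ambiguous: list[WeightedCluster] | None = None) -> ConsensusResult:
    tree = tree_from_clusters(
        [wc.cluster for wc in included],
        ts,
        supports={wc.cluster: wc.weight for wc in included},
    )
    return ConsensusResult(tree, list(included), method, list(ambiguous or []))


def _greedy_accept(
    candidates: list[WeightedCluster],
    accepted: list[WeightedCluster],
    resolved_target: int,
) -> list[WeightedCluster]:
    chosen = list(accepted)
    for wc in candidates:
        if len(chosen) >= resolved_target:
            break
        if any(wc.cluster == a.cluster for a in chosen):
            continue
        if all(are_compatible(wc.cluster, a.cluster) for a in chosen):
            chosen.append(wc)
    return chosen


def bootstrap_majority(
    coll: GeneTreeCollection, cutoff: float = 50.0, mode: str = "C"
) -> ConsensusResult:
    """Clusters with average support strictly above ``cutoff`` percent.

    At cutoff >= 50 the selected clusters are guaranteed pairwise compatible;
    below 50 the guarantee fails and compatibility is enforced greedily in
    descending weight order.
    """
    ranked = rank_clusters(coll, mode)
    above = [wc for wc in ranked if wc.weight > cutoff]
    if cutoff >= 50.0:
        included = above
    else:
        included = _greedy_accept(above, [], len(coll.taxon_set) - 3)
    return _build(included, coll.taxon_set, "bm")


def bootstrap_extended_majority(
    coll: GeneTreeCollection, cutoff: float = 50.0, mode: str = "C"
) -> ConsensusResult:
    """Majority clusters plus compatible remainder in descending weight order."""
    ranked = rank_clusters(coll, mode)
    majority = bootstrap_majority(coll, cutoff, mode).included
    rest = [wc for wc in ranked if wc not in majority]
    included = _greedy_accept(rest, majority, len(coll.taxon_set) - 3)
    return _build(included, coll.taxon_set, "bem")


def nelson_consensus(
    coll: GeneTreeCollection, mode: str = "C", max_candidates: int = NELSON_DEFAULT_CAP
) -> ConsensusResult:
    """Maximum-total-weight clique(s) of the cluster compatibility graph.

    The search is exact (all maximal cliques of the compatibility graph are
    enumerated; every maximum-weight clique is maximal because weights are
    nonnegative and scores of unreplicated clusters also count).  Instances
    with more than ``max_candidates`` distinct clusters are refused because
    the underlying problem is NP-hard.
    """
    ranked = rank_clusters(coll, mode)
    if len(ranked) > max_candidates:
        raise TreeError(
            f"{len(ranked)} candidate clusters exceed the exact-search cap "
            f"({max_candidates})"
        )
    if not ranked:
        return _build([], coll.taxon_set, "nelson")
    g = nx.Graph()
    g.add_nodes_from(range(len(ranked)))
    for i in range(len(ranked)):
        for j in range(i + 1, len(ranked)):
            if are_compatible(ranked[i].cluster, ranked[j].cluster):
                g.add_edge(i, j)
    best_score = -math.inf
    best: list[frozenset[int]] = []
    for clique in nx.find_cliques(g):
        score = sum(ranked[i].weight for i in clique)
        if score > best_score + 1e-9:
            best_score = score
            best = [frozenset(clique)]
        elif abs(score - best_score) <= 1e-9:
            best.append(frozenset(clique))
    common = frozenset.intersection(*best)
    union = frozenset.union(*best)
    included = [ranked[i] for i in sorted(common)]
    ambiguous = [ranked[i] for i in sorted(union - common)]
    return _build(included, coll.taxon_set, "nelson", ambiguous)


def weighted_extended_majority(
    ranked: list[WeightedCluster], taxon_set: TaxonSet
) -> ConsensusResult:
    """Greedy top-down accretion of mutually compatible ranked clusters.

    Stops once the tree is fully resolved (m - 3 nontrivial splits) or the
    ranking is exhausted.
    """
    if not isinstance(taxon_set, TaxonSet):
        raise TreeError("taxon_set must be a TaxonSet")
    included = _greedy_accept(list(ranked), [], len(taxon_set) - 3)
    return _build(included, taxon_set, "wem")
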