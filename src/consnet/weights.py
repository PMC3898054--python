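"""Overall cluster weights from branch supports and tree weights.

Three weighting modes are supported, all normalized by the total number of
trees ``n`` (trees lacking the cluster contribute zero):

* mode ``C``  — average of the cluster's branch supports over all trees;
* mode ``T``  — average of the weights of the trees containing the cluster;
* mode ``CT`` — average of (branch support x tree weight) products.

Weights stay on the percent scale of the input supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import Cluster, GeneTreeCollection, TreeError, extract_clusters

__all__ = ["WeightedCluster", "cluster_weight", "all_cluster_weights", "rank_clusters"]

MODES = ("C", "T", "CT")


@dataclass(frozen=True)
class WeightedCluster:
    cluster: Cluster
    weight: float
    mode: str
    member_trees: tuple[int, ...]
    per_tree_support: dict[int, float] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.member_trees:
            raise TreeError("a weighted cluster must occur in at least one tree")


def _check_mode(coll: GeneTreeCollection, mode: str) -> None:
    if mode not in MODES:
        raise TreeError(f"unknown weight mode {mode!r}")
    if mode in ("C", "CT") and not coll.has_supports:
        raise TreeError(f"mode {mode} requires branch supports on every tree")
    if mode in ("T", "CT") and coll.tree_weights is None:
        raise TreeError(f"mode {mode} requires per-tree weights")


def _occurrence(coll: GeneTreeCollection) -> dict[Cluster, dict[int, float]]:
    """cluster -> {tree index: branch support} over the whole collection."""
    occ: dict[Cluster, dict[int, float]] = {}
    sides: dict[Cluster, Cluster] = {}
    for j, t in enumerate(coll.trees):
        for c, sup in extract_clusters(t):
            rep = sides.setdefault(c, c)  # keep the first-seen observed side
            occ.setdefault(rep, {})[j] = 0.0 if sup is None else float(sup)
    return occ


def _weigh(
    c: Cluster, supports: dict[int, float], coll: GeneTreeCollection, mode: str
) -> WeightedCluster:
    n = coll.n
    if mode == "C":
        total = sum(supports.values())
    elif mode == "T":
        total = sum(coll.weight(j) for j in supports)
    else:
        total = sum(s * coll.weight(j) for j, s in supports.items())
    return WeightedCluster(
        cluster=c,
        weight=total / n,
        mode=mode,
        member_trees=tuple(sorted(supports)),
        per_tree_support=dict(supports),
    )


def cluster_weight(
    cluster: Cluster, coll: GeneTreeCollection, mode: str = "C"
) -> WeightedCluster:
    """Overall weight of one cluster across the collection."""
    _check_mode(coll, mode)
    occ = _occurrence(coll)
    supports = occ.get(cluster)
    if not supports:
        raise TreeError(f"{cluster} does not occur in any tree of the collection")
    return _weigh(cluster, supports, coll, mode)


def all_cluster_weights(
    coll: GeneTreeCollection, mode: str = "C"
) -> dict[Cluster, WeightedCluster]:
    _check_mode(coll, mode)
    occ = _occurrence(coll)
    return {c: _weigh(c, sup, coll, mode) for c, sup in occ.items()}


def rank_clusters(coll: GeneTreeCollection, mode: str = "C") -> list[WeightedCluster]:
    """All distinct clusters, ranked by descending overall weight.

    Ties break deterministically: more member trees first, then the
    lexicographically smaller canonical bit-vector.
    """
    weighted = all_cluster_weights(coll, mode)
    return sorted(
        weighted.values(),
        key=lambda wc: (-wc.weight, -len(wc.member_trees), wc.cluster.mask),
    )
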