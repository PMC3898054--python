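"""Explicit weighted consensus networks.

A network is a backbone tree (weight-based consensus tree, or a supplied
species tree) plus an ordered list of directed, weighted reticulation
branches.  Candidate clusters are processed in descending weight order; a
candidate is admitted as a reticulation when it has the first degree of
incompatibility with the current network state, i.e. with the tree obtained
from the backbone by applying the SPR moves of all previously accepted
reticulations.  Direction is decided by comparing support-weighted cumulative
Robinson-Foulds distances between the two SPR interpretations of the event
and the gene trees containing the united cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .trees import (
    Cluster,
    GeneTreeCollection,
    Phylogeny,
    TreeError,
    are_compatible,
    rf_distance,
    spr_move,
    spr_witnesses,
)
from .weights import WeightedCluster, rank_clusters
from .consensus import weighted_extended_majority

__all__ = [
    "ReticulationEdge",
    "ConsensusNetwork",
    "NetworkBuildConfig",
    "find_direction",
    "build_network_from_genetrees",
    "build_hgt_network",
    "add_reticulations",
]


@dataclass
class ReticulationEdge:
    """A directed, weighted reticulation branch between two backbone branches.

    ``source`` is the donor side, ``target`` the recipient side; when the
    direction rule ties the edge is ``undirected`` and the roles are
    arbitrary.  ``interval`` (1-based inclusive) is set only for events found
    by the sliding-window scan.
    """

    source: Optional[Cluster]
    target: Cluster
    direction: str  # forward | backward | undirected
    weight: float
    order_index: int = 0
    interval: Optional[tuple[int, int]] = None
    cluster: Optional[Cluster] = None  # the admitted cluster (source U target)
    no_evidence: bool = False  # direction rule had no gene tree to consult

    def __post_init__(self):
        if self.weight <= 0:
            raise TreeError("reticulation weight must be positive")
        if self.direction not in ("forward", "backward", "undirected"):
            raise TreeError(f"bad direction {self.direction!r}")


@dataclass
class ConsensusNetwork:
    backbone: Phylogeny
    reticulations: list[ReticulationEdge]
    cutoff: float

    @property
    def r(self) -> int:
        return len(self.reticulations)


@dataclass
class NetworkBuildConfig:
    cutoff: float = 10.0
    max_reticulations: Optional[int] = None
    weight_mode: str = "C"
    allow_undirected: bool = True
    witness_sides: str = "cluster"  # or "either" for unrooted inputs

    def __post_init__(self):
        if not 0 < self.cutoff <= 100:
            raise TreeError("cutoff must lie in (0, 100]")


def _tree_weight_for_direction(coll: GeneTreeCollection, j: int) -> float:
    return coll.weight(j)


def find_direction(
    backbone: Phylogeny,
    c1,
    c2,
    coll: GeneTreeCollection,
) -> tuple[str, bool]:
    """Orient a reticulation between backbone branches ``c1`` and ``c2``.

    ``c1`` and ``c2`` are disjoint side masks (or Clusters) of branches of
    ``backbone``.  T1 realizes the transfer c1 -> c2 (the recipient ``c2``
    subtree moves next to the donor branch ``c1``); T2 the opposite.  The
    support-weighted cumulative RF distance from each interpretation to the
    gene trees containing the united cluster decides: smaller distance wins.
    Returns ``(direction, no_evidence)`` where direction is ``forward`` when
    c1 is the donor, ``backward`` when c2 is, and ``undirected`` on a tie.
    """
    ts = backbone.taxon_set
    m1 = c1.side if isinstance(c1, Cluster) else int(c1)
    m2 = c2.side if isinstance(c2, Cluster) else int(c2)
    if m1 & m2:
        raise TreeError("reticulation endpoints must be disjoint")
    t1 = spr_move(backbone, m2, m1)  # c2 moves next to c1 (c1 donor)
    t2 = spr_move(backbone, m1, m2)  # c1 moves next to c2 (c2 donor)
    union = Cluster(ts, m1 | m2) if 0 < (m1 | m2) < ts.full_mask else None
    d1 = d2 = 0.0
    seen = False
    for j, gt in enumerate(coll.trees):
        if union is not None and union not in gt.split_set():
            continue
        seen = True
        w = _tree_weight_for_direction(coll, j)
        d1 += w * rf_distance(t1, gt)
        d2 += w * rf_distance(t2, gt)
    if not seen:
        return "undirected", True
    if abs(d1 - d2) <= 1e-9:
        return "undirected", False
    return ("forward", False) if d1 < d2 else ("backward", False)


def _witness_scores(
    state: Phylogeny,
    witnesses: list[tuple[int, int]],
    evidence: list[tuple[float, frozenset]],
) -> dict[tuple[int, int], tuple[float, Phylogeny]]:
    """Support-weighted cumulative RF of each witness SPR to the gene trees.

    ``evidence`` holds (tree weight, split set) of the gene trees containing
    the candidate cluster.  The witness whose interpretation is closest to
    that evidence identifies the event's branches, exactly as the direction
    rule compares the two orientations of a transfer.
    """
    out: dict[tuple[int, int], tuple[float, Phylogeny]] = {}
    for s_mask, target in witnesses:
        try:
            result = spr_move(state, s_mask, target)
        except TreeError:
            continue
        splits = result.split_set()
        score = sum(w * len(splits ^ ss) for w, ss in evidence)
        out[(s_mask, target)] = (score, result)
    return out


def add_reticulations(
    backbone: Phylogeny,
    ranked: list[WeightedCluster],
    coll: GeneTreeCollection,
    cfg: NetworkBuildConfig,
) -> ConsensusNetwork:
    """Greedy admission of first-degree-incompatible clusters above cutoff."""
    state = backbone.copy()
    ts = state.taxon_set
    edges: list[ReticulationEdge] = []
    accepted: set[Cluster] = set()
    gene_splits = [t.split_set() for t in coll.trees]
    for wc in ranked:
        if wc.weight < cfg.cutoff:
            break  # ranked is sorted descending
        if cfg.max_reticulations is not None and len(edges) >= cfg.max_reticulations:
            break
        c = wc.cluster
        if c in accepted or c in state.split_set():
            continue
        if all(are_compatible(c, s) for s in state.split_set()):
            continue  # compatible clusters are not reticulations
        witnesses = spr_witnesses(c, state, sides=cfg.witness_sides)
        if not witnesses:
            continue  # second or higher degree of incompatibility: skip
        evidence = [
            (coll.weight(j), gene_splits[j])
            for j in range(coll.n)
            if c in gene_splits[j]
        ]
        scored = _witness_scores(state, witnesses, evidence)
        if not scored:
            continue
        (s_mask, target), (d1, result) = min(
            scored.items(),
            key=lambda kv: (kv[1][0], min(kv[0][0].bit_count(), kv[0][1].bit_count()), kv[0]),
        )
        reverse = scored.get((target, s_mask))
        no_evidence = not evidence
        if no_evidence or reverse is None:
            direction = "undirected"
            no_evidence = True
        elif abs(d1 - reverse[0]) <= 1e-9:
            direction = "undirected"
        else:
            direction = "forward"  # chosen orientation is strictly better
        if direction == "undirected" and not cfg.allow_undirected:
            continue
        # the moved subtree is the recipient, the attach side the donor
        edge = ReticulationEdge(
            source=Cluster(ts, target), target=Cluster(ts, s_mask),
            direction=direction, weight=wc.weight,
            order_index=len(edges) + 1, cluster=c, no_evidence=no_evidence,
        )
        state = result
        accepted.add(c)
        edges.append(edge)
    return ConsensusNetwork(backbone, edges, cfg.cutoff)


def build_network_from_genetrees(
    coll: GeneTreeCollection, cfg: NetworkBuildConfig | None = None
) -> ConsensusNetwork:
    """Consensus network from gene trees alone.

    The backbone is the weight-based extended majority rule consensus tree;
    remaining clusters above the cutoff join as reticulations.
    """
    cfg = cfg or NetworkBuildConfig()
    if coll.n < 2:
        raise TreeError("a consensus network needs at least two gene trees")
    ranked = rank_clusters(coll, cfg.weight_mode)
    backbone = weighted_extended_majority(ranked, coll.taxon_set).tree
    backbone_splits = backbone.split_set()
    remaining = [wc for wc in ranked if wc.cluster not in backbone_splits]
    return add_reticulations(backbone, remaining, coll, cfg)


def build_hgt_network(
    species: Phylogeny,
    coll: GeneTreeCollection,
    cfg: NetworkBuildConfig | None = None,
) -> ConsensusNetwork:
    """Horizontal gene transfer network over a fixed, rooted species tree.

    The species tree is the backbone and is never altered by the gene signal;
    weighted gene tree clusters above the cutoff that are one SPR away from
    the current network state become directed transfer branches.
    """
    cfg = cfg or NetworkBuildConfig()
    if not species.rooted:
        raise TreeError("the species tree must be rooted")
    if species.taxon_set != coll.taxon_set:
        raise TreeError("species tree and gene trees use different taxon sets")
    ranked = rank_clusters(coll, cfg.weight_mode)
    backbone_splits = species.split_set()
    remaining = [wc for wc in ranked if wc.cluster not in backbone_splits]
    return add_reticulations(species, remaining, coll, cfg)
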