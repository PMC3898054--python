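"""Distance-based fallback tree inference with bootstrap supports.

This keeps the pipeline self-contained when no externally inferred trees are
available: p-distance / JC69 / K2P distances, classical neighbor-joining and
site-resampled bootstrap supports.  Externally produced Newick trees remain
first-class inputs elsewhere.

Bootstrap resampling is expressed through multinomial column weights against
per-pair mismatch indicators computed once per alignment, which makes a
replicate a pair of matrix-vector products instead of a fresh alignment pass.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .trees import Cluster, Phylogeny, TaxonSet, TreeError

__all__ = [
    "DistanceModel",
    "distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "SaturationWarning",
]


class SaturationWarning(UserWarning):
    """A pairwise distance correction was undefined; p-distance used instead."""


@dataclass(frozen=True)
class DistanceModel:
    kind: str = "jc69"  # p | jc69 | k2p
    alphabet: str = "dna"  # dna | aa (p only)

    def __post_init__(self):
        if self.kind not in ("p", "jc69", "k2p"):
            raise TreeError(f"unknown distance model {self.kind!r}")
        if self.alphabet not in ("dna", "aa"):
            raise TreeError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "aa" and self.kind != "p":
            raise TreeError("amino acid distances support the p model only")


_DNA = {c: i for i, c in enumerate("ACGT")}
_AA = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")}


def _encode(msa, model: DistanceModel) -> np.ndarray:
    """Rows in taxon-set order; unknown/gap characters encoded as -1."""
    lookup = _DNA if model.alphabet == "dna" else _AA
    arr = np.full((len(msa.taxon_set), msa.length), -1, dtype=np.int8)
    for i, lab in enumerate(msa.taxon_set.labels):
        seq = msa.sequences[lab].upper()
        arr[i] = [lookup.get(ch, -1) for ch in seq]
    return arr


class _PairwiseCounts:
    """Per-site mismatch indicators for every taxon pair."""

    def __init__(self, msa, model: DistanceModel):
        arr = _encode(msa, model)
        m = arr.shape[0]
        if m < 3:
            raise TreeError("a distance matrix needs at least 3 sequences")
        self.m = m
        self.model = model
        pairs = list(itertools.combinations(range(m), 2))
        i_idx = np.fromiter((i for i, _ in pairs), dtype=int)
        j_idx = np.fromiter((j for _, j in pairs), dtype=int)
        self.i_idx, self.j_idx = i_idx, j_idx
        valid = arr >= 0
        self.ok = (valid[i_idx] & valid[j_idx]).astype(np.float64)
        self.diff = (
            (arr[i_idx] != arr[j_idx]) & valid[i_idx] & valid[j_idx]
        ).astype(np.float64)
        if model.kind == "k2p":
            # transitions are A<->G (codes 0,2) and C<->T (codes 1,3)
            is_ag = (arr == 0) | (arr == 2)
            self.ts = (
                (arr[i_idx] != arr[j_idx])
                & valid[i_idx]
                & valid[j_idx]
                & (is_ag[i_idx] == is_ag[j_idx])
            ).astype(np.float64)
        else:
            self.ts = None

    def distances(self, weights: np.ndarray, warn: bool = True) -> np.ndarray:
        n_ok = self.ok @ weights
        if np.any(n_ok == 0):
            raise TreeError("a sequence pair shares no unambiguous site")
        p = (self.diff @ weights) / n_ok
        kind = self.model.kind
        with np.errstate(invalid="ignore", divide="ignore"):
            if kind == "p":
                dist = p
            elif kind == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                dist = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), p)
                if warn and np.any(arg <= 0):
                    warnings.warn(
                        "JC69 saturated for some pairs; p-distance used",
                        SaturationWarning,
                    )
            else:
                ts = (self.ts @ weights) / n_ok
                tv = p - ts
                a1 = 1.0 - 2.0 * ts - tv
                a2 = 1.0 - 2.0 * tv
                good = (a1 > 0) & (a2 > 0)
                dist = np.where(
                    good,
                    -0.5 * np.log(np.maximum(a1, 1e-300))
                    - 0.25 * np.log(np.maximum(a2, 1e-300)),
                    p,
                )
                if warn and np.any(~good):
                    warnings.warn(
                        "K2P saturated for some pairs; p-distance used",
                        SaturationWarning,
                    )
        d = np.zeros((self.m, self.m))
        d[self.i_idx, self.j_idx] = dist
        d[self.j_idx, self.i_idx] = dist
        return d


def distance_matrix(msa, model: DistanceModel | None = None) -> np.ndarray:
    """Symmetric pairwise distances with pairwise deletion of gaps/ambiguity."""
    model = model or DistanceModel()
    pc = _PairwiseCounts(msa, model)
    return pc.distances(np.ones(msa.length))


def nj_tree(d: np.ndarray, taxon_set: TaxonSet) -> Phylogeny:
    """Saitou-Nei neighbor joining; recovers additive topologies exactly."""
    d = np.asarray(d, dtype=float)
    m = d.shape[0]
    if d.shape != (m, m) or not np.allclose(d, d.T):
        raise TreeError("distance matrix must be square and symmetric")
    if m != len(taxon_set):
        raise TreeError("matrix size does not match taxon set")
    if m < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")

    g = nx.Graph()
    nodes = list(range(m))
    for nid, lab in enumerate(taxon_set.labels):
        g.add_node(nid, taxon=lab)
    next_id = m
    dm = np.zeros((2 * m, 2 * m))
    dm[:m, :m] = d
    active = list(range(m))

    while len(active) > 3:
        idx = np.array(active)
        sub = dm[np.ix_(idx, idx)]
        k = len(active)
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = dm[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        g.add_node(next_id)
        g.add_edge(next_id, i, length=max(li, 0.0), support=None)
        g.add_edge(next_id, j, length=max(lj, 0.0), support=None)
        rest = [a for a in active if a not in (i, j)]
        dm[next_id, rest] = dm[rest, next_id] = 0.5 * (
            dm[i, rest] + dm[j, rest] - dij
        )
        active = rest + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    hub = next_id
    g.add_node(hub)
    for node, length in ((a, la), (b, lb), (c, lc)):
        g.add_edge(hub, node, length=max(length, 0.0), support=None)

    return Phylogeny(g, taxon_set, rooted=False, root=hub, has_supports=False)


def bootstrap_supports(
    msa,
    model: DistanceModel | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> Phylogeny:
    """NJ point estimate with percent bootstrap supports on its splits."""
    if replicates < 1:
        raise TreeError("at least one bootstrap replicate is required")
    model = model or DistanceModel()
    rng = np.random.default_rng(seed)
    pc = _PairwiseCounts(msa, model)
    L = msa.length
    point = nj_tree(pc.distances(np.ones(L)), msa.taxon_set)
    counts: dict[Cluster, int] = {c: 0 for c in point.split_set()}
    probs = np.full(L, 1.0 / L)
    for _ in range(replicates):
        w = rng.multinomial(L, probs).astype(float)
        try:
            rep_tree = nj_tree(pc.distances(w, warn=False), msa.taxon_set)
        except TreeError:
            continue
        for c in rep_tree.split_set():
            if c in counts:
                counts[c] += 1
    n_trivial = len(msa.taxon_set) - 2
    for parent, child, mask in point.oriented_edges():
        size = mask.bit_count()
        if size < 2 or size > n_trivial:
            continue
        c = Cluster(msa.taxon_set, mask)
        point.graph.edges[parent, child]["support"] = (
            100.0 * counts.get(c, 0) / replicates
        )
    point.has_supports = True
    return point
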