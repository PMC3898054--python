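"""Phylogenetic tree and split (bipartition) primitives.

Trees are stored as undirected :mod:`networkx` graphs whose leaf nodes carry a
``taxon`` attribute and whose edges carry optional ``length`` and ``support``
attributes.  Splits are represented as bit-vectors over a fixed
:class:`TaxonSet`; the canonical form of an unrooted split stores the side
that does *not* contain the first taxon, so each bipartition has exactly one
representation.

The module provides Newick I/O (parsing delegated to dendropy), split
extraction, split-compatibility algebra, tree popping (building the unique
tree realising a compatible split set), Robinson-Foulds distance, subtree
prune-and-regraft (SPR) moves, and the first-degree-of-incompatibility test
that decides whether a single SPR move can make a tree display a given
cluster.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "TaxonSet",
    "Cluster",
    "Phylogeny",
    "GeneTreeCollection",
    "TreeError",
    "parse_newick",
    "write_newick",
    "extract_clusters",
    "are_compatible",
    "tree_from_clusters",
    "rf_distance",
    "spr_move",
    "spr_witnesses",
    "first_degree_incompatible",
    "all_spr_neighbors",
    "read_tree_collection",
]


class TreeError(ValueError):
    """Raised on malformed trees, taxon mismatches or illegal tree operations."""


class TaxonSet:
    """Ordered set of unique taxon labels; the order fixes bit positions."""

    __slots__ = ("labels", "_index", "_hash")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if any(not isinstance(x, str) or not x for x in labels):
            raise TreeError("taxon labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate taxon labels: {dup}")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._hash = hash(labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"

    def index(self, label: str) -> int:
        return self._index[label]

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self._index[lab]
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self.labels) if mask >> i & 1)


class Cluster:
    """A split of the taxon set, canonicalized to the side excluding taxon #1.

    Identity (equality/hashing) is that of the unrooted bipartition.  The
    side the cluster was observed as (the descendant side of the branch in
    its tree of origin) is kept in ``side``: SPR moves "induced by" a cluster
    assemble that side, which is what distinguishes a first-degree from a
    second-degree incompatibility in the worked examples.
    """

    __slots__ = ("taxon_set", "mask", "side")

    def __init__(self, taxon_set: TaxonSet, mask: int):
        full = taxon_set.full_mask
        if mask <= 0 or mask >= full:
            raise TreeError("cluster side must be a proper non-empty subset")
        self.side = mask  # the observed side, as given
        if mask & 1:  # canonicalize: store the side without the first taxon
            mask = full ^ mask
        self.taxon_set = taxon_set
        self.mask = mask

    @classmethod
    def from_labels(cls, taxon_set: TaxonSet, labels: Iterable[str]) -> "Cluster":
        return cls(taxon_set, taxon_set.mask_of(labels))

    @property
    def size(self) -> int:
        return self.mask.bit_count()

    @property
    def complement_mask(self) -> int:
        return self.taxon_set.full_mask ^ self.mask

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.taxon_set.labels_of(self.mask)

    @property
    def side_taxa(self) -> tuple[str, ...]:
        return self.taxon_set.labels_of(self.side)

    def is_trivial(self) -> bool:
        """True for splits with a side of fewer than two taxa (pendant edges)."""
        return min(self.size, len(self.taxon_set) - self.size) < 2

    def compatible_with(self, other: "Cluster") -> bool:
        return are_compatible(self, other)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Cluster)
            and self.mask == other.mask
            and self.taxon_set == other.taxon_set
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.taxon_set))

    def __repr__(self) -> str:
        return f"Cluster({{{','.join(self.taxa)}}})"


def are_compatible(a: Cluster, b: Cluster) -> bool:
    """Standard split compatibility: some pair of opposite sides is disjoint."""
    if a.taxon_set != b.taxon_set:
        raise TreeError("clusters are defined on different taxon sets")
    full = a.taxon_set.full_mask
    am, bm = a.mask, b.mask
    return (
        am & bm == 0
        or am & ~bm & full == 0
        or ~am & full & bm == 0
        or am | bm == full
    )


class Phylogeny:
    """Leaf-labelled tree over a :class:`TaxonSet`.

    ``graph`` is an undirected tree; leaf nodes carry ``taxon`` attributes,
    edges carry ``length`` (float or None) and ``support`` (percent, float or
    None).  ``rooted`` marks whether the designated ``root`` node is
    biologically meaningful; all split algebra treats the topology as
    unrooted.
    """

    def __init__(
        self,
        graph: nx.Graph,
        taxon_set: TaxonSet,
        *,
        rooted: bool = False,
        root: Optional[int] = None,
        has_supports: bool = False,
    ):
        self.graph = graph
        self.taxon_set = taxon_set
        self.rooted = rooted
        self.root = root
        self.has_supports = has_supports
        self._validate()

    def _validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() and not nx.is_tree(g):
            raise TreeError("topology must be an acyclic connected graph")
        seen = {}
        for node, data in g.nodes(data=True):
            lab = data.get("taxon")
            if lab is not None:
                if lab in seen:
                    raise TreeError(f"duplicate leaf label {lab!r}")
                if lab not in self.taxon_set:
                    raise TreeError(f"leaf {lab!r} not in taxon set")
                seen[lab] = node
        if set(seen) != set(self.taxon_set.labels):
            missing = sorted(set(self.taxon_set.labels) - set(seen))
            raise TreeError(f"leaves do not match taxon set; missing {missing}")

    # -- structure helpers -------------------------------------------------

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            self.graph.copy(),
            self.taxon_set,
            rooted=self.rooted,
            root=self.root,
            has_supports=self.has_supports,
        )

    def leaf_nodes(self) -> dict[str, int]:
        return {
            d["taxon"]: n for n, d in self.graph.nodes(data=True) if "taxon" in d
        }

    def _start_node(self) -> int:
        # the parse/construction root is kept even for unrooted trees so that
        # split extraction reports the descendant side the input displayed
        if self.root is not None and self.root in self.graph:
            return self.root
        first = self.leaf_nodes()[self.taxon_set.labels[0]]
        if self.graph.degree(first) == 0:
            return first
        return next(iter(self.graph[first]))

    def oriented_edges(self) -> list[tuple[int, int, int]]:
        """Every edge once as ``(parent, child, child_side_mask)``.

        Orientation is away from a deterministic start node, so the child
        mask is the leaf set of the component on the far side of the edge.
        """
        g = self.graph
        start = self._start_node()
        order = list(nx.dfs_edges(g, start))
        ts = self.taxon_set
        masks: dict[int, int] = {
            n: (1 << ts.index(d["taxon"])) for n, d in g.nodes(data=True) if "taxon" in d
        }
        out: list[tuple[int, int, int]] = []
        # reversed preorder visits children before parents
        for parent, child in reversed(order):
            m = masks.setdefault(child, 0)
            out.append((parent, child, m))
            masks[parent] = masks.get(parent, 0) | m
        return out

    def edge_sides(self) -> set[int]:
        """All side masks of all edges (both orientations), trivial included."""
        full = self.taxon_set.full_mask
        sides: set[int] = set()
        for _, _, m in self.oriented_edges():
            sides.add(m)
            sides.add(full ^ m)
        sides.discard(0)
        sides.discard(full)
        return sides

    def splits_with_supports(self) -> list[tuple[Cluster, Optional[float]]]:
        """Nontrivial splits with their branch supports, deduplicated."""
        found: dict[int, tuple[int, Optional[float]]] = {}
        g = self.graph
        for parent, child, mask in self.oriented_edges():
            key = _canonical_mask(mask, self.taxon_set)
            size = mask.bit_count()
            if size < 2 or size > len(self.taxon_set) - 2:
                continue
            sup = g.edges[parent, child].get("support")
            if key not in found or (found[key][1] is None and sup is not None):
                found[key] = (mask, sup)
        return [
            (Cluster(self.taxon_set, side), s)
            for _, (side, s) in sorted(found.items())
        ]

    def split_set(self) -> frozenset[Cluster]:
        return frozenset(c for c, _ in self.splits_with_supports())

    def is_binary(self) -> bool:
        """Fully resolved as an unrooted tree: m - 3 nontrivial splits."""
        return len(self.split_set()) == max(len(self.taxon_set) - 3, 0)

    def __repr__(self) -> str:
        return f"<Phylogeny {len(self.taxon_set)} taxa, {len(self.split_set())} splits>"


def _canonical_mask(mask: int, taxon_set: TaxonSet) -> int:
    return taxon_set.full_mask ^ mask if mask & 1 else mask


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_SUPPORT_COMMENT = re.compile(r"&?support\s*=\s*([0-9.eE+-]+)")


def _support_from_dendropy(nd, support_scale: str) -> Optional[float]:
    if support_scale == "none":
        return None
    val: Optional[float] = None
    label = getattr(nd, "label", None)
    if label is not None:
        try:
            val = float(label)
        except ValueError:
            val = None
    if val is None:
        for comment in getattr(nd, "comments", []) or []:
            m = _SUPPORT_COMMENT.search(comment)
            if m:
                val = float(m.group(1))
                break
    if val is None:
        return None
    if support_scale == "probability":
        val *= 100.0
    return val


def parse_newick(
    text: str,
    support_scale: str = "percent",
    taxon_set: Optional[TaxonSet] = None,
    rooted: Optional[bool] = None,
) -> Phylogeny:
    """Parse one Newick tree.

    ``support_scale`` is one of ``percent``, ``probability``, ``auto`` or
    ``none``; supports are normalized to the 0-100 percent scale internally.
    If ``taxon_set`` is given the tree must contain exactly those taxa;
    otherwise the taxon order is taken from the leaf order of this tree.
    """
    import dendropy

    if support_scale not in ("percent", "probability", "none", "auto"):
        raise TreeError(f"unknown support scale {support_scale!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    leaves = [nd.taxon.label for nd in dtree.leaf_node_iter()]
    if len(leaves) != len(set(leaves)):
        raise TreeError("duplicate leaf labels in Newick input")
    if len(leaves) < 3:
        raise TreeError("a tree needs at least 3 taxa")
    if taxon_set is None:
        taxon_set = TaxonSet(leaves)
    elif set(leaves) != set(taxon_set.labels):
        raise TreeError("tree taxa do not match the established taxon set")

    if support_scale == "auto":
        vals = [
            _support_from_dendropy(nd, "percent")
            for nd in dtree.preorder_node_iter()
            if not nd.is_leaf()
        ]
        vals = [v for v in vals if v is not None]
        support_scale = "probability" if vals and max(vals) <= 1.0 else "percent"

    g = nx.Graph()
    counter = itertools.count()

    def build(nd) -> int:
        nid = next(counter)
        if nd.is_leaf():
            g.add_node(nid, taxon=nd.taxon.label)
        else:
            g.add_node(nid)
        for child in nd.child_nodes():
            cid = build(child)
            sup = None if child.is_leaf() else _support_from_dendropy(child, support_scale)
            g.add_edge(nid, cid, length=child.edge.length, support=sup)
        return nid

    root = build(dtree.seed_node)
    if rooted is None:
        rooted = bool(dtree.is_rooted)

    if not rooted:
        root = _suppress_degree_two(g, root)

    has_supports = any(
        d.get("support") is not None for _, _, d in g.edges(data=True)
    )
    return Phylogeny(
        g, taxon_set, rooted=rooted, root=root, has_supports=has_supports
    )


def _suppress_degree_two(g: nx.Graph, root: int) -> int:
    """Contract internal degree-2 nodes (unrooting a rooted Newick)."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 2 and "taxon" not in g.nodes[n]:
                (a, da), (b, db) = [(nbr, g.edges[n, nbr]) for nbr in g[n]]
                la, lb = da.get("length"), db.get("length")
                length = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
                support = da.get("support")
                if support is None:
                    support = db.get("support")
                g.remove_node(n)
                g.add_edge(a, b, length=length, support=support)
                if root == n:
                    root = a
                changed = True
    return root


def _fmt_num(x: float) -> str:
    x = float(x)
    if x == int(x):
        return str(int(x))
    return repr(round(x, 10))


def write_newick(
    t: Phylogeny, *, include_supports: bool = True, include_lengths: bool = True
) -> str:
    """Serialize to Newick with supports as internal node labels."""
    g = t.graph
    ts = t.taxon_set
    minlab: dict[int, int] = {}

    start = t.root if (t.rooted and t.root is not None) else t._start_node()
    if "taxon" in g.nodes[start] and g.degree(start) > 0:
        start = next(iter(g[start]))  # never render from a leaf: its label would vanish
    order = list(nx.dfs_edges(g, start))
    children: dict[int, list[int]] = {}
    for p, c in order:
        children.setdefault(p, []).append(c)
    # deterministic output: order children by smallest taxon index beneath
    for p, c in reversed(order):
        m = minlab.get(c, ts.index(g.nodes[c]["taxon"]) if "taxon" in g.nodes[c] else len(ts))
        minlab[c] = m
        minlab[p] = min(minlab.get(p, len(ts)), m)

    def render(node: int, parent: Optional[int]) -> str:
        kids = sorted(children.get(node, []), key=lambda c: minlab.get(c, len(ts)))
        if not kids:
            body = g.nodes[node]["taxon"]
        else:
            inner = ",".join(render(c, node) for c in kids)
            body = f"({inner})"
            if include_supports and parent is not None:
                sup = g.edges[parent, node].get("support")
                if sup is not None:
                    body += _fmt_num(sup)
        if include_lengths and parent is not None:
            length = g.edges[parent, node].get("length")
            if length is not None:
                body += f":{_fmt_num(length)}"
        return body

    return render(start, None) + ";"


# ---------------------------------------------------------------------------
# Split operations
# ---------------------------------------------------------------------------

def extract_clusters(t: Phylogeny) -> list[tuple[Cluster, Optional[float]]]:
    """Nontrivial splits of ``t`` with their branch supports."""
    return t.splits_with_supports()


def tree_from_clusters(
    clusters: Iterable[Cluster],
    taxon_set: Optional[TaxonSet] = None,
    supports: Optional[dict[Cluster, float]] = None,
) -> Phylogeny:
    """Tree popping: the unique (multifurcating) tree displaying the splits.

    Raises :class:`TreeError` when the splits are not pairwise compatible.
    """
    clusters = list(clusters)
    if taxon_set is None:
        if not clusters:
            raise TreeError("taxon_set is required for an empty cluster set")
        taxon_set = clusters[0].taxon_set
    for c in clusters:
        if c.taxon_set != taxon_set:
            raise TreeError("clusters are defined on different taxon sets")
    for a, b in itertools.combinations(clusters, 2):
        if not are_compatible(a, b):
            raise TreeError(f"incompatible clusters {a} / {b}")

    masks = sorted({c.mask for c in clusters}, key=lambda m: (-m.bit_count(), m))
    g = nx.Graph()
    counter = itertools.count()
    root = next(counter)
    g.add_node(root)
    node_of: dict[int, int] = {}
    parent_of: dict[int, Optional[int]] = {}
    sup_of = {c.mask: supports[c] for c in clusters if supports and c in supports}

    for m in masks:
        parent = None  # smallest strict superset already placed
        for other in masks:
            if other != m and other & m == m:
                if parent is None or other & parent == other:
                    parent = other
        nid = next(counter)
        g.add_node(nid)
        pnode = root if parent is None else node_of[parent]
        g.add_edge(pnode, nid, length=None, support=sup_of.get(m))
        node_of[m] = nid
        parent_of[m] = parent

    for i, lab in enumerate(taxon_set.labels):
        bit = 1 << i
        host = None
        for m in masks:
            if m & bit and (host is None or m & host == m):
                host = m
        nid = next(counter)
        g.add_node(nid, taxon=lab)
        g.add_edge(root if host is None else node_of[host], nid, length=None, support=None)

    root = _suppress_degree_two(g, root)
    return Phylogeny(
        g, taxon_set, rooted=False, root=root,
        has_supports=supports is not None and bool(supports),
    )


def rf_distance(t1: Phylogeny, t2: Phylogeny) -> int:
    """Robinson-Foulds distance: |symmetric difference of nontrivial splits|."""
    if t1.taxon_set != t2.taxon_set:
        raise TreeError("trees are defined on different taxon sets")
    return len(t1.split_set() ^ t2.split_set())


# ---------------------------------------------------------------------------
# SPR moves and first-degree incompatibility
# ---------------------------------------------------------------------------

def _as_side_mask(x, taxon_set: TaxonSet) -> int:
    if isinstance(x, Cluster):
        if x.taxon_set != taxon_set:
            raise TreeError("cluster on a different taxon set")
        return x.mask
    return int(x)


def spr_move(t: Phylogeny, prune, regraft_edge) -> Phylogeny:
    """Prune the subtree on the ``prune`` side and regraft it onto an edge.

    ``prune`` is a Cluster or side mask identifying one side of an edge of
    ``t`` (the component that moves).  ``regraft_edge`` identifies an edge of
    the remaining tree by one of its side masks (restricted to the remaining
    taxa).  A branch keeps its support exactly when its bipartition is
    unchanged by the move; branches whose bipartition changed get none.
    """
    ts = t.taxon_set
    full = ts.full_mask
    prune_mask = _as_side_mask(prune, ts)
    g = t.graph.copy()
    orig_supports: dict[int, Optional[float]] = {}
    for parent, child, mask in t.oriented_edges():
        sup = g.edges[parent, child].get("support")
        if sup is not None:
            orig_supports[_canonical_mask(mask, ts)] = sup

    edge = None
    for parent, child, mask in t.oriented_edges():
        if mask == prune_mask:
            edge = (parent, child)
            break
        if (full ^ mask) == prune_mask:
            edge = (child, parent)
            break
    if edge is None:
        raise TreeError("prune side is not a subtree of the tree")
    anchor, moved = edge
    moved_len = g.edges[anchor, moved].get("length")
    g.remove_edge(anchor, moved)
    if g.degree(anchor) == 2 and "taxon" not in g.nodes[anchor]:
        (a, da), (b, db) = [(nbr, g.edges[anchor, nbr]) for nbr in g[anchor]]
        la, lb = da.get("length"), db.get("length")
        length = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
        g.remove_node(anchor)
        g.add_edge(a, b, length=length, support=None)

    remaining_mask = full ^ prune_mask
    rg_raw = _as_side_mask(regraft_edge, ts)
    rg = rg_raw & remaining_mask
    if rg == 0 or rg == remaining_mask:
        raise TreeError("regraft edge lies inside the pruned subtree")

    remaining_nodes = _component(g, _any_remaining(g, moved))
    target = None
    oriented = _oriented_edges_of(g.subgraph(remaining_nodes), ts)
    for parent, child, mask in oriented:
        if mask == rg or mask == (remaining_mask ^ rg):
            target = (parent, child)
            break
    if target is None:
        raise TreeError("regraft edge not found in the remaining tree")

    p, q = target
    edata = g.edges[p, q]
    length = edata.get("length")
    half = None if length is None else length / 2.0
    w = max(g.nodes) + 1
    g.remove_edge(p, q)
    g.add_node(w)
    g.add_edge(p, w, length=half, support=None)
    g.add_edge(w, q, length=half, support=None)
    g.add_edge(w, moved, length=moved_len, support=None)
    result = Phylogeny(g, ts, rooted=False, root=None, has_supports=t.has_supports)
    for parent, child, mask in result.oriented_edges():
        g.edges[parent, child]["support"] = orig_supports.get(_canonical_mask(mask, ts))
    return result


def _component(g: nx.Graph, node: int) -> set[int]:
    return nx.node_connected_component(g, node)


def _any_remaining(g: nx.Graph, moved: int) -> int:
    moved_comp = _component(g, moved)
    for n in g:
        if n not in moved_comp:
            return n
    raise TreeError("pruning removed the whole tree")


def _oriented_edges_of(g: nx.Graph, ts: TaxonSet) -> list[tuple[int, int, int]]:
    start = next(iter(g.nodes))
    order = list(nx.dfs_edges(g, start))
    masks: dict[int, int] = {
        n: (1 << ts.index(d["taxon"])) for n, d in g.nodes(data=True) if "taxon" in d
    }
    out = []
    for parent, child in reversed(order):
        m = masks.setdefault(child, 0)
        out.append((parent, child, m))
        masks[parent] = masks.get(parent, 0) | m
    return out


def _is_compatible_with_tree(c: Cluster, t: Phylogeny) -> bool:
    return all(are_compatible(c, s) for s in t.split_set())


def spr_witnesses(
    c: Cluster, t: Phylogeny, sides: str = "cluster"
) -> list[tuple[int, int]]:
    """All ``(moved_side, attach_side)`` pairs whose single SPR displays ``c``.

    A pair ``(S, D)`` means: pruning the subtree with leaf side ``S`` and
    regrafting it onto the edge of the remaining tree whose side is ``D``
    yields a tree in which ``S`` and ``D`` unite into the cluster's side.
    With ``sides="cluster"`` only moves assembling the cluster's observed
    side are considered (the moves the cluster induces); ``sides="either"``
    also allows assembling the complement, appropriate when the input trees
    carry no meaningful root.  Returns the empty list when ``c`` is
    compatible with ``t`` (no move needed) or needs more than one move.
    """
    ts = t.taxon_set
    if c.taxon_set != ts:
        raise TreeError("cluster on a different taxon set")
    if sides not in ("cluster", "either"):
        raise TreeError(f"unknown side policy {sides!r}")
    if _is_compatible_with_tree(c, t):
        return []
    full = ts.full_mask
    edge_sides = t.edge_sides()
    assemble = [c.side] if sides == "cluster" else [c.side, full ^ c.side]
    witnesses: set[tuple[int, int]] = set()
    for a_side in assemble:
        for s in edge_sides:
            if s & a_side != s or s == a_side:
                continue  # need S a strict subset of the assembled side
            rem = full ^ s
            boundary = a_side & ~s  # the region S must join
            restricted = {x & rem for x in edge_sides}
            restricted.discard(0)
            restricted.discard(rem)
            if boundary not in restricted:
                continue
            # attaching S onto any edge inside the region creates the split;
            # the attach side names the donor branch of the event
            for x in restricted:
                if x & boundary == x:
                    witnesses.add((s, x))
    ordered = sorted(
        witnesses,
        key=lambda w: (min(w[0].bit_count(), w[1].bit_count()), w[0], w[1]),
    )
    return ordered


def first_degree_incompatible(
    c: Cluster, t: Phylogeny, sides: str = "cluster"
) -> bool:
    """True iff ``c`` is incompatible with ``t`` but one induced SPR fixes it."""
    if _is_compatible_with_tree(c, t):
        return False
    return bool(spr_witnesses(c, t, sides=sides))


def all_spr_neighbors(t: Phylogeny) -> list[Phylogeny]:
    """Every distinct topology one SPR move away from ``t`` (brute force)."""
    full = t.taxon_set.full_mask
    seen: dict[frozenset, Phylogeny] = {}
    origin = t.split_set()
    for s in sorted(t.edge_sides()):
        rem = full ^ s
        if rem.bit_count() < 2:
            continue
        for target in _remaining_edge_sides(t, s):
            try:
                nb = spr_move(t, s, target)
            except TreeError:
                continue
            key = frozenset(nb.split_set())
            if key != frozenset(origin) and key not in seen:
                seen[key] = nb
    return list(seen.values())


def _remaining_edge_sides(t: Phylogeny, prune_mask: int) -> list[int]:
    full = t.taxon_set.full_mask
    rem = full ^ prune_mask
    out = set()
    for side in t.edge_sides():
        x = side & rem
        if 0 < x < rem:
            out.add(min(x, rem ^ x))
    return sorted(out)


# ---------------------------------------------------------------------------
# Gene tree collections
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeCollection:
    """A list of trees over one taxon set, with optional per-tree weights."""

    trees: list[Phylogeny]
    tree_weights: Optional[list[float]] = None
    taxon_set: TaxonSet = field(init=False)

    def __post_init__(self):
        if not self.trees:
            raise TreeError("empty tree collection")
        self.taxon_set = self.trees[0].taxon_set
        for t in self.trees:
            if t.taxon_set != self.taxon_set:
                raise TreeError("all trees must share one taxon set")
        if self.tree_weights is not None:
            if len(self.tree_weights) != len(self.trees):
                raise TreeError("one weight per tree is required")
            if any(w < 0 for w in self.tree_weights):
                raise TreeError("tree weights must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.trees)

    def weight(self, j: int) -> float:
        return 1.0 if self.tree_weights is None else self.tree_weights[j]

    @property
    def has_supports(self) -> bool:
        return all(t.has_supports for t in self.trees)


_WEIGHT_TOKEN = re.compile(r"^weight=([0-9.eE+-]+)\s+")


def read_tree_collection(
    lines: Iterable[str],
    support_scale: str = "auto",
    taxon_set: Optional[TaxonSet] = None,
) -> GeneTreeCollection:
    """Read a tree-list stream: one Newick per line, optional ``weight=`` token.

    The taxon order is established by the first tree and enforced thereafter.
    """
    trees: list[Phylogeny] = []
    weights: list[Optional[float]] = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        w = None
        m = _WEIGHT_TOKEN.match(line)
        if m:
            w = float(m.group(1))
            line = line[m.end():]
        t = parse_newick(line, support_scale=support_scale, taxon_set=taxon_set)
        if taxon_set is None:
            taxon_set = t.taxon_set
        trees.append(t)
        weights.append(w)
    if not trees:
        raise TreeError("no trees found in input")
    given = [w for w in weights if w is not None]
    if given and len(given) != len(weights):
        raise TreeError("either all trees or none must carry a weight= token")
    return GeneTreeCollection(trees, tree_weights=list(given) if given else None)
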