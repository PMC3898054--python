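import numpy as np
import pytest

from consnet.networks import (
    ConsensusNetwork,
    NetworkBuildConfig,
    ReticulationEdge,
    build_hgt_network,
    build_network_from_genetrees,
    find_direction,
)
from consnet.trees import (
    Cluster,
    GeneTreeCollection,
    TaxonSet,
    TreeError,
    parse_newick,
    rf_distance,
    spr_move,
)

from .conftest import random_binary_tree


class TestConfig:
    def test_cutoff_bounds(self):
        with pytest.raises(TreeError):
            NetworkBuildConfig(cutoff=0.0)
        with pytest.raises(TreeError):
            NetworkBuildConfig(cutoff=101.0)

    def test_edge_weight_must_be_positive(self, fig_taxa):
        with pytest.raises(TreeError):
            ReticulationEdge(
                source=None,
                target=Cluster.from_labels(fig_taxa, ["x", "y"]),
                direction="forward",
                weight=0.0,
            )


class TestAlgorithmOne:
    def test_fig_network(self, fig_collection, fig_taxa):
        net = build_network_from_genetrees(fig_collection, NetworkBuildConfig(cutoff=10))
        assert net.backbone.split_set() == {
            Cluster.from_labels(fig_taxa, ["z", "w"]),
            Cluster.from_labels(fig_taxa, ["x", "u"]),
        }
        assert net.r == 1
        edge = net.reticulations[0]
        assert edge.cluster == Cluster.from_labels(fig_taxa, ["x", "y"])
        assert edge.weight == pytest.approx(85.0 / 3)
        # the concurrent x<->y interpretations are symmetric
        assert edge.direction == "undirected"
        assert {edge.source, edge.target} == {
            Cluster(fig_taxa, fig_taxa.mask_of(["x"])),
            Cluster(fig_taxa, fig_taxa.mask_of(["y"])),
        }

    def test_identical_trees_no_reticulations(self):
        trees = [parse_newick("((a,b)90,(c,d)80,e);") for _ in range(3)]
        ts = trees[0].taxon_set
        trees = [parse_newick("((a,b)90,(c,d)80,e);", taxon_set=ts) for _ in range(3)]
        net = build_network_from_genetrees(GeneTreeCollection(trees))
        assert net.r == 0

    def test_single_tree_rejected(self, fig_taxa):
        coll = GeneTreeCollection([parse_newick("((x,y)50,(z,w)50,u);", taxon_set=fig_taxa)])
        with pytest.raises(TreeError):
            build_network_from_genetrees(coll)

    def test_two_topologies_spr_oracle(self):
        ts = TaxonSet(list("abcdef"))
        majority = "(((a,b)90,c)90,(d,e)90,f);"
        minority = "(((a,b)90,f)90,c,(d,e)90);"  # f moved next to (a,b)
        trees = [parse_newick(majority, taxon_set=ts)] * 2 + [
            parse_newick(minority, taxon_set=ts)
        ]
        net = build_network_from_genetrees(
            GeneTreeCollection(list(trees)), NetworkBuildConfig(cutoff=10)
        )
        assert net.r == 1
        edge = net.reticulations[0]
        moved = spr_move(net.backbone, edge.target.side, edge.source.side)
        minority_tree = parse_newick(minority, taxon_set=ts)
        assert edge.cluster in moved.split_set()
        assert rf_distance(moved, minority_tree) == 0

    def test_reticulation_weights_non_increasing(self):
        rng = np.random.default_rng(17)
        ts = TaxonSet([f"s{i}" for i in range(8)])
        trees = []
        for _ in range(6):
            t = random_binary_tree(8, rng, ts)
            for p, c, mask in t.oriented_edges():
                if 2 <= mask.bit_count() <= 6:
                    t.graph.edges[p, c]["support"] = float(rng.integers(30, 101))
            t.has_supports = True
            trees.append(t)
        net = build_network_from_genetrees(
            GeneTreeCollection(trees), NetworkBuildConfig(cutoff=5)
        )
        weights = [e.weight for e in net.reticulations]
        assert weights == sorted(weights, reverse=True)
        assert all(w >= 5 for w in weights)

    def test_raising_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(29)
        ts = TaxonSet([f"s{i}" for i in range(8)])
        trees = []
        for _ in range(6):
            t = random_binary_tree(8, rng, ts)
            for p, c, mask in t.oriented_edges():
                if 2 <= mask.bit_count() <= 6:
                    t.graph.edges[p, c]["support"] = float(rng.integers(0, 101))
            t.has_supports = True
            trees.append(t)
        coll = GeneTreeCollection(trees)
        lo = build_network_from_genetrees(coll, NetworkBuildConfig(cutoff=5))
        hi = build_network_from_genetrees(coll, NetworkBuildConfig(cutoff=30))
        lo_keys = [(e.cluster, e.source, e.target) for e in lo.reticulations]
        hi_keys = [(e.cluster, e.source, e.target) for e in hi.reticulations]
        assert hi_keys == lo_keys[: len(hi_keys)]

    def test_spr_interpretation_stays_valid(self):
        rng = np.random.default_rng(31)
        ts = TaxonSet([f"s{i}" for i in range(8)])
        trees = []
        for _ in range(6):
            t = random_binary_tree(8, rng, ts)
            for p, c, mask in t.oriented_edges():
                if 2 <= mask.bit_count() <= 6:
                    t.graph.edges[p, c]["support"] = float(rng.integers(0, 101))
            t.has_supports = True
            trees.append(t)
        net = build_network_from_genetrees(
            GeneTreeCollection(trees), NetworkBuildConfig(cutoff=5)
        )
        state = net.backbone
        for edge in net.reticulations:
            state = spr_move(state, edge.target.side, edge.source.side)
            assert edge.cluster in state.split_set()

    def test_max_reticulations_cap(self, fig_collection):
        net = build_network_from_genetrees(
            fig_collection, NetworkBuildConfig(cutoff=10, max_reticulations=0)
        )
        assert net.r == 0


class TestFindDirection:
    def test_collection_equal_to_t1_gives_forward(self):
        ts = TaxonSet(list("abcdef"))
        backbone = parse_newick(
            "(((a,b),c),(d,e),f);", support_scale="none", taxon_set=ts
        )
        # the tree that results from moving a next to d (d donor, a recipient)
        t1 = spr_move(backbone, ts.mask_of(["a"]), ts.mask_of(["d"]))
        coll = GeneTreeCollection([t1])
        direction, warn = find_direction(
            backbone, ts.mask_of(["d"]), ts.mask_of(["a"]), coll
        )
        assert direction == "forward"
        assert not warn

    def test_symmetric_transfers_undirected(self, fig_collection, fig_taxa):
        backbone = parse_newick("((x,u),(z,w),y);", support_scale="none", taxon_set=fig_taxa)
        direction, warn = find_direction(
            backbone, fig_taxa.mask_of(["x"]), fig_taxa.mask_of(["y"]), fig_collection
        )
        assert direction == "undirected"
        assert not warn

    def test_no_evidence_flag(self, fig_taxa):
        backbone = parse_newick("((x,u),(z,w),y);", support_scale="none", taxon_set=fig_taxa)
        coll = GeneTreeCollection(
            [parse_newick("((x,u)90,(z,w)100,y);", taxon_set=fig_taxa)]
        )
        direction, warn = find_direction(
            backbone, fig_taxa.mask_of(["z"]), fig_taxa.mask_of(["y"]), coll
        )
        assert direction == "undirected"
        assert warn

    def test_matches_independent_rf_sums(self):
        rng = np.random.default_rng(41)
        ts = TaxonSet([f"s{i}" for i in range(6)])
        checked = 0
        for _ in range(60):
            backbone = random_binary_tree(6, rng, ts)
            sides = sorted(backbone.edge_sides())
            pairs = [
                (a, b)
                for a in sides
                for b in sides
                if a < b and a & b == 0 and (a | b) != ts.full_mask
            ]
            if not pairs:
                continue
            c1, c2 = pairs[rng.integers(0, len(pairs))]
            trees = [random_binary_tree(6, rng, ts) for _ in range(5)]
            coll = GeneTreeCollection(trees)
            direction, warn = find_direction(backbone, c1, c2, coll)
            union = Cluster(ts, c1 | c2)
            t1 = spr_move(backbone, c2, c1)
            t2 = spr_move(backbone, c1, c2)
            d1 = sum(rf_distance(t1, t) for t in trees if union in t.split_set())
            d2 = sum(rf_distance(t2, t) for t in trees if union in t.split_set())
            has = any(union in t.split_set() for t in trees)
            if not has:
                assert direction == "undirected" and warn
            elif d1 < d2:
                assert direction == "forward"
            elif d1 > d2:
                assert direction == "backward"
            else:
                assert direction == "undirected"
            checked += 1
        assert checked >= 30


class TestAlgorithmThree:
    def _species(self, newick, ts=None):
        return parse_newick(newick, support_scale="none", taxon_set=ts, rooted=True)

    def test_species_equal_gene_trees_no_transfers(self, fig_taxa):
        species = self._species("((x,y),(z,w),u);", fig_taxa)
        genes = GeneTreeCollection(
            [parse_newick("((x,y)80,(z,w)90,u);", taxon_set=fig_taxa)] * 2
        )
        net = build_hgt_network(species, genes)
        assert net.r == 0
        assert net.backbone.split_set() == species.split_set()

    def test_unrooted_species_tree_rejected(self, fig_collection, fig_taxa):
        species = parse_newick("((x,y),(z,w),u);", support_scale="none", taxon_set=fig_taxa)
        with pytest.raises(TreeError):
            build_hgt_network(species, fig_collection)

    def test_taxon_mismatch_rejected(self, fig_collection):
        species = self._species("((a,b),(c,d),e);")
        with pytest.raises(TreeError):
            build_hgt_network(species, fig_collection)

    def test_single_moved_taxon_transfer(self):
        ts = TaxonSet(list("abcdefg"))
        species = self._species("((((a,b),c),d),((e,f),g));", ts)
        # gene tree: a transferred next to e
        gene = "(((b,c)95,d)95,(((e,a)95,f)95,g)95);"
        genes = GeneTreeCollection([parse_newick(gene, taxon_set=ts)] * 2)
        net = build_hgt_network(species, genes, NetworkBuildConfig(cutoff=10))
        assert net.r >= 1
        endpoint_pairs = [
            {e.source, e.target} for e in net.reticulations
        ]
        assert {
            Cluster(ts, ts.mask_of(["a"])),
            Cluster(ts, ts.mask_of(["e"])),
        } in endpoint_pairs
        assert net.backbone.split_set() == species.split_set()

    def test_eq1_weight_example(self):
        # species tree plus 4 gene trees; 3 share one conflicting cluster at
        # supports 80/70/60 -> (80+70+60)/4 = 52.5, retained at cutoff 30
        ts = TaxonSet(list("abcde"))
        species = self._species("(((a,b),c),(d,e));", ts)
        conflicting = "((a,c){s},(d,e){s},b);"
        genes = [
            parse_newick(conflicting.format(s=80), taxon_set=ts),
            parse_newick(conflicting.format(s=70), taxon_set=ts),
            parse_newick(conflicting.format(s=60), taxon_set=ts),
            parse_newick("((a,b)99,(d,e)99,c);", taxon_set=ts),
        ]
        net = build_hgt_network(
            species, GeneTreeCollection(genes), NetworkBuildConfig(cutoff=30)
        )
        ac = Cluster.from_labels(ts, ["a", "c"])
        edge = next(e for e in net.reticulations if e.cluster == ac)
        assert edge.weight == pytest.approx(52.5)

    def test_backbone_never_altered(self, fig_taxa):
        species = self._species("((x,z),(y,w),u);", fig_taxa)
        genes = GeneTreeCollection(
            [parse_newick("((x,y)90,(z,w)90,u);", taxon_set=fig_taxa)] * 3
        )
        net = build_hgt_network(species, genes, NetworkBuildConfig(cutoff=5))
        assert net.backbone.split_set() == species.split_set()
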