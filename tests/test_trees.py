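"""Dendrograms, orthology/taxonomy trees, RF distance and percentile."""

from __future__ import annotations

import numpy as np
import pytest
from conftest import enumerate_topologies, naive_single_linkage, oracle_rf

from homolineage.errors import (
    ContractError,
    DomainError,
    EmptyTreeError,
    TaxonomyLookupError,
)
from homolineage.grouping import groups_at_threshold
from homolineage.pairscore import HIGraph
from homolineage.trees import (
    cut_dendrogram,
    hi_dendrogram,
    leaf_labels,
    newick_from_string,
    orthology_tree,
    random_binary_topology,
    read_newick,
    read_nodes_dmp,
    read_taxonomy_table,
    rf_distance,
    rf_percentile,
    splits,
    taxonomy_tree,
    write_newick,
)


def _star_graph(his: dict[str, float]) -> HIGraph:
    g = HIGraph()
    for gene, hi in his.items():
        g.add_edge("focal", gene, hi)
    return g


class TestDendrogram:
    def test_cherry_merge_height(self):
        g = HIGraph()
        g.add_edge("a", "b", 0.8)
        tree = hi_dendrogram(g, {"a", "b"})
        root = tree.seed_node
        assert root.merge_hi == 0.8
        assert leaf_labels(tree) == {"a", "b"}
        # edge lengths live on the distance scale d = 1 - HI
        assert all(c.edge.length == pytest.approx(0.2) for c in root.child_nodes())

    def test_merge_order_matches_naive_agglomeration(self, rng):
        for _ in range(10):
            g = HIGraph()
            genes = [f"g{i}" for i in range(5)]
            # distinct edge weights -> unambiguous merge order
            his = list(rng.permutation(np.linspace(0.1, 0.95, 10)))
            k = 0
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(genes[i], genes[j], float(his[k]))
                    k += 1
            tree = hi_dendrogram(g, genes)
            merges = naive_single_linkage(g, genes)
            got = sorted(
                (n.merge_hi, frozenset(lf.taxon.label for lf in n.leaf_iter()))
                for n in tree.preorder_node_iter() if not n.is_leaf()
            )
            assert got == sorted((sim, mem) for sim, mem in merges)

    def test_cuts_reproduce_threshold_groups(self, rng, random_graph_factory):
        for _ in range(10):
            graph, smap = random_graph_factory(rng, n_genes=12)
            members = max(
                (g.members for g in groups_at_threshold(graph, 1e-9, smap)), key=len
            )
            tree = hi_dendrogram(graph, members)
            sub = graph.subgraph(members)
            for t in [0.0, *sub.distinct_his(), 1.0]:
                expected = {
                    g.members for g in groups_at_threshold(sub, t, smap)
                }
                assert set(cut_dendrogram(tree, t)) == expected

    def test_disconnected_members_rejected(self):
        g = HIGraph()
        g.add_edge("a", "b", 0.5)
        g.add_gene("c")
        with pytest.raises(DomainError):
            hi_dendrogram(g, {"a", "b", "c"})

    def test_unknown_member_rejected(self):
        with pytest.raises(DomainError):
            hi_dendrogram(HIGraph(), {"nope"})


class TestOrthologyTree:
    SMAP = {
        "focal": ("sp0", ""),
        "a1": ("sp1", ""), "a2": ("sp1", ""),
        "b1": ("sp2", ""), "c1": ("sp3", ""),
    }

    def test_star_caterpillar_orders_by_hi(self):
        g = _star_graph({"a1": 0.9, "b1": 0.6, "c1": 0.3})
        tree = orthology_tree(g, "focal", self.SMAP)
        assert leaf_labels(tree) == {"sp0", "sp1", "sp2", "sp3"}
        # successive merge heights follow the star HIs
        heights = sorted(
            (n.merge_hi for n in tree.preorder_node_iter() if not n.is_leaf()),
            reverse=True,
        )
        assert heights == [0.9, 0.6, 0.3]

    def test_best_gene_per_species_with_lexicographic_ties(self):
        g = _star_graph({"a1": 0.7, "a2": 0.7, "b1": 0.5})
        from homolineage.trees import species_representatives

        reps = species_representatives(g, "focal", self.SMAP)
        assert reps == {"sp0": "focal", "sp1": "a1", "sp2": "b1"}

    def test_focal_species_represented_by_focal_itself(self):
        smap = dict(self.SMAP)
        smap["sib"] = ("sp0", "")
        g = _star_graph({"a1": 0.9, "sib": 0.99})
        reps = __import__("homolineage.trees", fromlist=["x"]).species_representatives(
            g, "focal", smap
        )
        assert reps["sp0"] == "focal"

    def test_no_homologous_species_is_empty_tree(self):
        g = HIGraph()
        g.add_gene("focal")
        with pytest.raises(EmptyTreeError):
            orthology_tree(g, "focal", self.SMAP)


class TestTaxonomy:
    TSV = (
        "root\tA\n"
        "root\tB\n"
        "A\ts1\n"
        "A\ts2\n"
        "B\tpoly\n"
        "poly\ts3\n"
        "poly\ts4\n"
        "poly\ts5\n"
    )

    def _table(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(self.TSV)
        return read_taxonomy_table(path)

    def test_two_species_cherry(self, tmp_path):
        tree = taxonomy_tree(self._table(tmp_path), {"s1", "s2"})
        assert leaf_labels(tree) == {"s1", "s2"}
        assert splits(tree) == set()

    def test_trifurcation_preserved(self, tmp_path):
        tree = taxonomy_tree(self._table(tmp_path), {"s1", "s2", "s3", "s4", "s5"})
        # the poly node keeps all three children unresolved
        degrees = sorted(len(n.child_nodes()) for n in tree.preorder_node_iter()
                         if not n.is_leaf())
        assert 3 in degrees
        assert splits(tree) == {frozenset({"s3", "s4", "s5"})}

    def test_unresolvable_labels_listed(self, tmp_path):
        with pytest.raises(TaxonomyLookupError, match="zz"):
            taxonomy_tree(self._table(tmp_path), {"s1", "zz"})

    def test_bipartitions_match_ancestor_oracle(self, tmp_path):
        """Induced-tree splits equal a brute-force computation from
        ancestor paths: two kept species are on the same side of a
        split iff their LCA is below the split's node."""
        table = self._table(tmp_path)
        keep = ["s1", "s2", "s3", "s4", "s5"]
        tree = taxonomy_tree(table, keep)

        parent = {r.child: r.parent for r in table.records}

        def ancestors(x):
            path = [x]
            while x in parent:
                x = parent[x]
                path.append(x)
            return path

        expected = set()
        for node in {a for s in keep for a in ancestors(s)}:
            side = frozenset(s for s in keep if node in ancestors(s))
            if 2 <= len(side) <= len(keep) - 2:
                ref = min(keep)
                expected.add(frozenset(set(keep) - side) if ref in side else side)
        assert splits(tree) == expected

    def test_nodes_dmp_dialect(self, tmp_path):
        path = tmp_path / "nodes.dmp"
        path.write_text(
            "1\t|\t1\t|\tno rank\t|\n"
            "2\t|\t1\t|\tkingdom\t|\n"
            "3\t|\t2\t|\tspecies\t|\n"
            "4\t|\t2\t|\tspecies\t|\n"
        )
        table = read_nodes_dmp(path)
        assert table.root == "1"
        tree = taxonomy_tree(table, {"3", "4"})
        assert leaf_labels(tree) == {"3", "4"}


class TestRF:
    def test_identical_trees_distance_zero(self):
        nwk = "((a,(b,c)),((d,e),(f,(g,h))));"
        assert rf_distance(newick_from_string(nwk), newick_from_string(nwk)) == 0

    def test_four_leaf_distance_two(self):
        a = newick_from_string("((a,b),(c,d));")
        b = newick_from_string("((a,c),(b,d));")
        assert rf_distance(a, b) == 2

    def test_unequal_leaf_sets_rejected_with_listing(self):
        a = newick_from_string("((a,b),(c,d));")
        b = newick_from_string("((a,b),(c,e));")
        with pytest.raises(ContractError, match="e"):
            rf_distance(a, b)

    @pytest.mark.parametrize("n", [4, 5])
    def test_all_pairs_match_dendropy_oracle(self, n):
        labels = [f"t{i}" for i in range(n)]
        tops = enumerate_topologies(labels)
        for x in tops:
            for y in tops:
                mine = rf_distance(newick_from_string(x + ";"),
                                   newick_from_string(y + ";"))
                assert mine == oracle_rf(x + ";", y + ";")

    def test_random_pairs_match_oracle_and_bound(self, rng):
        labels = [f"t{i}" for i in range(8)]
        seen_max = 0
        for _ in range(40):
            a = random_binary_topology(labels, rng)
            b = random_binary_topology(labels, rng)
            d = rf_distance(a, b)
            assert d == oracle_rf(a.as_string(schema="newick"),
                                  b.as_string(schema="newick"))
            assert 0 <= d <= 2 * (len(labels) - 3)
            seen_max = max(seen_max, d)
        assert seen_max == 2 * (len(labels) - 3)  # the bound is attainable

    def test_metric_axioms_on_sampled_triples(self, rng):
        labels = [f"t{i}" for i in range(7)]
        for _ in range(20):
            a, b, c = (random_binary_topology(labels, rng) for _ in range(3))
            assert rf_distance(a, b) == rf_distance(b, a)
            assert rf_distance(a, a) == 0
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


class TestPercentile:
    def test_zero_rf_scores_hundred(self, rng):
        ref = random_binary_topology([f"t{i}" for i in range(6)], rng)
        assert rf_percentile(0, ref, n_random=500, seed=1).percentile == 100.0

    def test_needs_four_leaves(self):
        with pytest.raises(DomainError):
            rf_percentile(0, newick_from_string("(a,b,c);"), n_random=10, seed=0)

    def test_percentile_counts_ge_observed(self):
        """With a 4-leaf reference (3 topologies: self at rf 0, two at
        rf 2), percentile(2) must equal the sampled fraction of trees
        at rf >= 2, i.e. about 2/3."""
        ref = newick_from_string("((a,b),(c,d));")
        res = rf_percentile(2, ref, n_random=3000, seed=7)
        assert res.percentile == pytest.approx(100 * 2 / 3, abs=3.0)

    def test_sampler_is_uniform_over_topologies(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        counts = {frozenset(splits(newick_from_string(t + ";"))): 0
                  for t in enumerate_topologies(labels)}
        n = 3000
        for _ in range(n):
            counts[frozenset(splits(random_binary_topology(labels, rng)))] += 1
        assert len(counts) == 15
        expected = n / 15
        assert all(abs(c - expected) < 5 * np.sqrt(expected) for c in counts.values())


class TestNewickIO:
    def test_roundtrip_with_comment(self, tmp_path, rng):
        tree = random_binary_topology([f"sp_{i}" for i in range(6)], rng)
        path = tmp_path / "t.nwk"
        write_newick(tree, path, comment="seed=1")
        back = read_newick(path)
        assert leaf_labels(back) == leaf_labels(tree)
        assert rf_distance(back, tree) == 0
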