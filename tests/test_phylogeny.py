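import math

import numpy as np
import pytest

from dhhkit.alignment import Alignment
from dhhkit.errors import ParseError, ValidationError
from dhhkit.phylogeny import (
    DistanceMatrix,
    PhyloConfig,
    bootstrap_support,
    distance_matrix,
    extract_major_clades,
    midpoint_root,
    neighbor_joining,
)
from dhhkit.tree import parse_newick

from oracles import random_additive_tree, tree_bipartitions_from_edges


def dm(ids, values, model="p"):
    return DistanceMatrix(tuple(ids), np.asarray(values, dtype=float), model)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDE"])
        D = distance_matrix(aln, "p")
        assert D.values[0, 1] == 0.0

    def test_half_mismatch_p(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACWY"])
        D = distance_matrix(aln, "p")
        assert D.values[0, 1] == pytest.approx(0.5)

    def test_poisson_closed_form(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACWY"])
        D = distance_matrix(aln, "poisson")
        assert D.values[0, 1] == pytest.approx(-math.log(0.5))

    def test_pairwise_deletion(self):
        # only 2 comparable columns; one mismatch -> p = 0.5
        aln = Alignment(["a", "b"], ["ACD-", "A-W-"])
        D = distance_matrix(aln, "p")
        assert D.values[0, 1] == pytest.approx(0.5)

    def test_no_comparable_columns_names_pair(self):
        aln = Alignment(["a", "b"], ["A-", "-C"])
        with pytest.raises(ValidationError, match="'a' and 'b'"):
            distance_matrix(aln, "p")

    def test_saturated_clamped(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        D = distance_matrix(aln, "poisson", max_distance=5.0)
        assert D.values[0, 1] == 5.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValidationError):
            dm(["a", "b"], [[0, 1], [2, 0]])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        D = dm(["a", "b", "c"], [[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        tree = neighbor_joining(D)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(dm(["a", "b"], [[0, 1], [1, 0]]))

    def test_four_taxon_additive_recovery(self, rng):
        spec, dist = random_additive_tree(4, rng)
        ids = spec["leaves"]
        values = [[dist[(i, j)] for j in ids] for i in ids]
        tree = neighbor_joining(dm(ids, values))
        names, got = tree.leaf_distance_matrix()
        for i in ids:
            for j in ids:
                assert got[(i, j)] == pytest.approx(dist[(i, j)], abs=1e-9)

    def test_identical_taxa_form_zero_cherry(self):
        ids = ["a", "b", "c", "d"]
        # a and b identical; c, d distinct
        values = [
            [0.0, 0.0, 1.0, 1.2],
            [0.0, 0.0, 1.0, 1.2],
            [1.0, 1.0, 0.0, 0.8],
            [1.2, 1.2, 0.8, 0.0],
        ]
        tree = neighbor_joining(dm(ids, values))
        cherry = [
            node
            for node in tree.preorder()
            if node.children
            and sorted(c.name for c in node.children if c.is_leaf) == ["a", "b"]
        ]
        assert cherry
        assert all(
            c.length == pytest.approx(0.0)
            for c in cherry[0].children
            if c.name in ("a", "b")
        )

    def test_additivity_property_random_trees(self, rng):
        # NJ recovers generating trees exactly from additive distances
        for _ in range(25):
            n = int(rng.integers(4, 13))
            spec, dist = random_additive_tree(n, rng)
            ids = spec["leaves"]
            values = [[dist[(i, j)] for j in ids] for i in ids]
            tree = neighbor_joining(dm(ids, values))
            expected = tree_bipartitions_from_edges(spec["edges"], ids)
            assert set(tree.bipartitions()) == expected
            _, got = tree.leaf_distance_matrix()
            for i in ids:
                for j in ids:
                    assert got[(i, j)] == pytest.approx(dist[(i, j)], abs=1e-8)


class TestMidpointRoot:
    def test_two_leaf_symmetric_split(self):
        tree = parse_newick("(A:1,B:2);", rooted=False)
        rooted = midpoint_root(tree)
        depths = sorted(
            (leaf.name, _depth(leaf)) for leaf in rooted.leaves()
        )
        assert depths[0][1] == pytest.approx(1.5)
        assert depths[1][1] == pytest.approx(1.5)

    def test_caterpillar_longest_path(self):
        tree = parse_newick("((((A:5,B:1):1,C:1):1,D:1):1,E:2);", rooted=False)
        rooted = midpoint_root(tree)
        # brute-force all-pairs longest path from the same newick
        names, dist = tree.leaf_distance_matrix()
        longest = max(dist.values())
        maxdepth = max(_depth(l) for l in rooted.leaves())
        assert maxdepth == pytest.approx(longest / 2)

    def test_node_coincident_midpoint_no_extra_edge(self):
        # path A..B has length 4, midpoint exactly on the internal node X
        tree = parse_newick("((A:2,B:2):1,C:1);", rooted=False)
        rooted = midpoint_root(tree)
        # root should be the node joining A and B: no zero-length child edges
        kids = {c.name: c.length for c in rooted.root.children if c.is_leaf}
        assert kids.get("A") == pytest.approx(2.0)
        assert kids.get("B") == pytest.approx(2.0)

    def test_equal_max_depths_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            spec, dist = random_additive_tree(n, rng)
            ids = spec["leaves"]
            values = [[dist[(i, j)] for j in ids] for i in ids]
            tree = neighbor_joining(
                DistanceMatrix(tuple(ids), np.asarray(values), "p")
            )
            rooted = midpoint_root(tree)
            depths = sorted(_depth(l) for l in rooted.leaves())
            assert abs(depths[-1] - max(dist.values()) / 2) <= 1e-9

    def test_all_zero_lengths_warns(self):
        tree = parse_newick("((A:0,B:0):0,C:0);", rooted=False)
        with pytest.warns(UserWarning):
            rooted = midpoint_root(tree)
        assert rooted.rooted


def _depth(node):
    d = 0.0
    while node.parent is not None:
        d += node.length
        node = node.parent
    return d


class TestBootstrap:
    def _blocky_alignment(self):
        # 8 rows in 4 clearly distinct pairs
        blocks = {
            "a": "AAAAAAAAAA",
            "b": "CCCCCCCCCC",
            "c": "DDDDDDDDDD",
            "d": "EEEEEEEEEE",
        }
        rows, ids = [], []
        for key, block in blocks.items():
            for i in (1, 2):
                ids.append(f"{key}{i}")
                mutated = block[:-1] + ("F" if i == 2 else block[-1])
                rows.append(mutated * 4)
        return Alignment(ids, rows)

    def test_zero_replicates_no_supports(self):
        aln = self._blocky_alignment()
        tree = bootstrap_support(aln, PhyloConfig(bootstrap_replicates=0), seed=1)
        assert all(n.support is None for n in tree.preorder())

    def test_strong_signal_high_support(self):
        aln = self._blocky_alignment()
        config = PhyloConfig(bootstrap_replicates=100)
        tree = bootstrap_support(aln, config, seed=42)
        supports = [n.support for n in tree.internal_edges() if n.support is not None]
        assert supports
        assert min(supports) >= 0.95

    def test_supports_in_unit_interval_and_reproducible(self):
        aln = self._blocky_alignment()
        config = PhyloConfig(bootstrap_replicates=50)
        t1 = bootstrap_support(aln, config, seed=7)
        t2 = bootstrap_support(aln, config, seed=7)
        s1 = [n.support for n in t1.preorder() if n.support is not None]
        s2 = [n.support for n in t2.preorder() if n.support is not None]
        assert s1 == s2
        assert all(0.0 <= s <= 1.0 for s in s1)

    def test_requires_four_rows(self):
        aln = Alignment(["a", "b", "c"], ["ACDE", "ACDF", "ACWW"])
        with pytest.raises(ValidationError):
            bootstrap_support(aln, PhyloConfig(bootstrap_replicates=10), seed=0)


class TestExtractMajorClades:
    def test_three_families_recovered(self, pipeline_result, default_dataset):
        clades = pipeline_result.clades
        assert len(clades) == 3
        for clade in clades:
            labels = {default_dataset.labels[m] for m in clade}
            assert len(labels) == 1

    def test_star_tree_returns_empty(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);", rooted=False)
        rooted = midpoint_root(tree)
        assert extract_major_clades(rooted, PhyloConfig(clade_min_size=5)) == []

    def test_min_size_gate(self):
        tree = parse_newick("((A:0.1,B:0.1):5,(C:0.1,D:0.1):5);")
        clades = extract_major_clades(tree, PhyloConfig(clade_min_size=10))
        assert clades == []

    def test_disjoint_union_subset(self, pipeline_result):
        clades = pipeline_result.clades
        union = set()
        for clade in clades:
            assert not (union & clade)
            union |= clade
        assert union <= set(pipeline_result.rooted_tree.leaf_names())

    def test_unrooted_rejected(self):
        tree = parse_newick("(A:1,B:1,C:1);", rooted=False)
        with pytest.raises(ValidationError):
            extract_major_clades(tree, PhyloConfig())


class TestNewick:
    def test_parse_two_leaf(self):
        tree = parse_newick("(A:1,B:2);")
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_round_trip_random_tree(self, rng):
        spec, dist = random_additive_tree(20, rng)
        ids = spec["leaves"]
        values = [[dist[(i, j)] for j in ids] for i in ids]
        tree = neighbor_joining(DistanceMatrix(tuple(ids), np.asarray(values), "p"))
        text = tree.to_newick()
        back = parse_newick(text, rooted=False)
        assert set(back.bipartitions()) == set(tree.bipartitions())
        _, d1 = tree.leaf_distance_matrix()
        _, d2 = back.leaf_distance_matrix()
        for key, value in d1.items():
            assert d2[key] == pytest.approx(value, abs=1e-5)

    def test_supports_round_trip(self):
        tree = parse_newick("((A:1,B:1)0.97:0.5,(C:1,D:1)0.88:0.5);")
        out = parse_newick(tree.to_newick())
        supports = sorted(
            n.support for n in out.preorder() if n.support is not None
        )
        assert supports == [0.88, 0.97]

    def test_unbalanced_parenthesis_error_with_offset(self):
        with pytest.raises(ParseError, match="offset"):
            parse_newick("((A:1,B:2;")

    def test_trailing_garbage_rejected(self):
        with pytest.raises(ParseError):
            parse_newick("(A:1,B:2); junk")
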