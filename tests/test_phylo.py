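import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishhealth.errors import InsufficientDataError, SaturationError
from fishhealth.model import AlignedSequences, DistanceMatrix, TreeNode, bipartitions
from fishhealth.phylo import (
    bootstrap_support,
    jc_distance_matrix,
    jukes_cantor,
    neighbor_joining,
    pairwise_stats,
)
from fishhealth.synthetic import simulate_alignment


class TestPairwiseStats:
    def test_identical_sequences(self):
        seqs = AlignedSequences([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        identity, p = pairwise_stats(seqs)[("a", "b")]
        assert identity == 100.0 and p == 0.0

    def test_single_difference(self):
        seqs = AlignedSequences([("a", "ACGT"), ("b", "ACGA")])
        identity, p = pairwise_stats(seqs)[("a", "b")]
        assert identity == 75.0 and p == 0.25

    def test_gap_sites_excluded_pairwise(self):
        seqs = AlignedSequences([("a", "AC-T"), ("b", "ACGT")])
        identity, p = pairwise_stats(seqs)[("a", "b")]
        assert identity == 100.0 and p == 0.0

    def test_n_sites_excluded(self):
        seqs = AlignedSequences([("a", "ACNT"), ("b", "ACGA")])
        identity, p = pairwise_stats(seqs)[("a", "b")]
        assert identity == pytest.approx(100 * 2 / 3)

    def test_all_gap_pair_omitted(self):
        seqs = AlignedSequences([("a", "--"), ("b", "AC"), ("c", "AC")])
        stats = pairwise_stats(seqs)
        assert ("a", "b") not in stats
        assert ("b", "c") in stats


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form_value(self):
        assert jukes_cantor(0.057) == pytest.approx(0.0593, abs=5e-5)
        assert jukes_cantor(0.057) == pytest.approx(
            -0.75 * math.log(1 - 4 * 0.057 / 3), rel=1e-12)

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    @given(p=st.floats(min_value=1e-6, max_value=0.74))
    @settings(max_examples=100, deadline=None)
    def test_correction_exceeds_p_and_is_monotone(self, p):
        d = jukes_cantor(p)
        assert d >= p
        assert jukes_cantor(p * 0.5) < d

    def test_small_p_limit(self):
        assert jukes_cantor(1e-7) == pytest.approx(1e-7, rel=1e-3)


def random_additive_tree(rng, n_taxa):
    """Random binary topology with random branch lengths, plus its exact
    leaf-to-leaf distance matrix (the brute-force tree-metric oracle)."""
    nodes = [TreeNode(name=f"T{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.uniform(0.05, 1.0)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    tree = TreeNode(children=nodes)
    labels = sorted(tree.leaf_names())
    paths = tree.path_lengths()
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), dist in paths.items():
        ia, ib = labels.index(a), labels.index(b)
        d[ia, ib] = d[ib, ia] = dist
    return tree, DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}  # AB|CD split
        paths = tree.path_lengths()
        for (a, b), expect in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert paths[(a, b)] == pytest.approx(expect, abs=1e-12)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.0)   # (2 + 3 - 5)/2
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_tie_break_deterministic_on_ultrametric_input(self):
        labels = list("ABCDE")
        d = np.full((5, 5), 2.0)
        np.fill_diagonal(d, 0.0)
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        t2 = neighbor_joining(DistanceMatrix(labels, d))
        assert t1.newick() == t2.newick()

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(77)
        for n_taxa in (4, 5, 6, 8):
            for _ in range(3):
                _, dm = random_additive_tree(rng, n_taxa)
                tree = neighbor_joining(dm)
                paths = tree.path_lengths()
                for i, a in enumerate(dm.labels):
                    for b in dm.labels[i + 1:]:
                        assert paths[(a, b)] == pytest.approx(
                            dm[(a, b)], abs=1e-9), (n_taxa, a, b)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(InsufficientDataError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, 1], [1, 0.0]])))


def six_taxon_tree(bl=0.1):
    def leaf(name):
        return TreeNode(name=name, length=bl)

    left = TreeNode(length=bl, children=[
        TreeNode(length=bl, children=[leaf("A"), leaf("B")]),
        leaf("C"),
    ])
    right = TreeNode(length=bl, children=[
        TreeNode(length=bl, children=[leaf("D"), leaf("E")]),
        leaf("F"),
    ])
    return TreeNode(children=[left, right, leaf("G")])


class TestBootstrap:
    def test_congruent_divergent_blocks_full_support(self):
        # two identical pairs separated at half of all sites (p = 0.5):
        # every resample carries the a,b | c,d signal
        seqs = AlignedSequences([
            ("a", "AAAAAACCCCCC"), ("b", "AAAAAACCCCCC"),
            ("c", "TTTTTTCCCCCC"), ("d", "TTTTTTCCCCCC"),
        ])
        tree = bootstrap_support(seqs, replicates=50, seed=1)
        internal = [n for n in _walk(tree) if n.support is not None]
        assert internal and all(n.support == 100 for n in internal)

    def test_single_replicate_supports_binary(self):
        rng_tree = six_taxon_tree()
        seqs = simulate_alignment(rng_tree, 500, seed=5)
        tree = bootstrap_support(seqs, replicates=1, seed=2)
        supports = {n.support for n in _walk(tree) if n.support is not None}
        assert supports <= {0, 100}

    def test_true_bipartitions_strongly_supported(self):
        truth = six_taxon_tree(bl=0.1)
        seqs = simulate_alignment(truth, 2000, seed=4)
        tree = bootstrap_support(seqs, replicates=200, seed=4)
        # drop G to compare 6-leaf splits (7 leaves incl. outgroup-ish G)
        true_splits = bipartitions(truth)
        est_splits = bipartitions(tree)
        assert true_splits <= est_splits  # topology recovered
        supports = [n.support for n in _walk(tree) if n.support is not None]
        assert all(s >= 90 for s in supports)

    def test_supports_invariant_to_taxon_order(self):
        truth = six_taxon_tree(bl=0.08)
        seqs = simulate_alignment(truth, 800, seed=6)
        reordered = AlignedSequences(list(reversed(seqs.records)))
        t1 = bootstrap_support(seqs, replicates=60, seed=3)
        t2 = bootstrap_support(reordered, replicates=60, seed=3)
        assert _support_map(t1) == _support_map(t2)

    def test_jc_distance_matrix_consistency(self):
        truth = six_taxon_tree(bl=0.05)
        seqs = simulate_alignment(truth, 10000, seed=9)
        dm = jc_distance_matrix(seqs)
        # A-B are separated by 0.1 expected substitutions/site
        assert dm[("A", "B")] == pytest.approx(0.1, abs=0.03)


def _walk(tree):
    yield tree
    for c in tree.children:
        yield from _walk(c)


def _support_map(tree):
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    out = {}

    def walk(node, is_root):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c, False) for c in node.children))
        if not is_root and node.support is not None:
            side = below if anchor not in below else all_leaves - below
            out[side] = node.support
        return below

    walk(tree, True)
    return out
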