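"""Neighbor joining, bootstrap support, and outgroup rooting."""

import itertools

import numpy as np
import pytest

from methanodiv.distances import DistanceModel, distance_matrix
from methanodiv.errors import TreeError
from methanodiv.io import Alignment, AlignmentRecord, DistanceMatrix
from methanodiv.phylogeny import (
    Tree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    root_with_outgroup,
    unroot,
)

from conftest import random_additive_tree


def _dm(values, labels):
    return DistanceMatrix(tuple(labels), np.asarray(values, dtype=float))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = _dm([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], "ABC")
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_recovery_and_brute_force(self, rng):
        labels, dist, bips, paths = random_additive_tree(4, rng)
        tree = neighbor_joining(_dm(dist, labels))
        assert tree.bipartitions() == bips
        recovered = tree.leaf_path_lengths()
        for k, v in paths.items():
            assert recovered[k] == pytest.approx(v, abs=1e-9)
        # brute force: the recovered split minimizes least-squares over all
        # 3 unrooted 4-taxon topologies (each split determines the fit)
        best_rss, best_split = None, None
        for pair in itertools.combinations(range(4), 2):
            i, j = pair
            k, l = [m for m in range(4) if m not in pair]
            # four-point condition residual for split {i,j}|{k,l}
            rss = (
                dist[i, k] + dist[j, l] - dist[i, l] - dist[j, k]
            ) ** 2
            if best_rss is None or rss < best_rss:
                best_rss, best_split = rss, frozenset({labels[i], labels[j]})
        expected = best_split
        all_leaves = frozenset(labels)
        if min(all_leaves) in expected:
            expected = all_leaves - expected
        assert tree.bipartitions() == {expected}

    def test_random_additive_trees_recovered(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            labels, dist, bips, paths = random_additive_tree(n, rng)
            tree = neighbor_joining(_dm(dist, labels))
            assert tree.bipartitions() == bips
            recovered = tree.leaf_path_lengths()
            for k, v in paths.items():
                assert recovered[k] == pytest.approx(v, abs=1e-9)
            # unrooted fully-resolved tree has 2n - 3 edges
            assert tree.n_edges() == 2 * n - 3

    def test_skbio_cross_check(self, rng):
        """Topology agrees with scikit-bio's independent NJ implementation."""
        import skbio

        for seed in range(5):
            local = np.random.default_rng(seed)
            n = 8
            labels, dist, _, _ = random_additive_tree(n, local)
            # perturb slightly so the matrix is generic (non-additive)
            noise = local.uniform(0, 0.01, size=dist.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            v = dist + noise
            ours = neighbor_joining(_dm(v, labels))
            theirs = skbio.tree.nj(
                skbio.DistanceMatrix(v, ids=labels)
            )
            their_bips = set()
            all_leaves = frozenset(labels)
            ref = min(all_leaves)
            for node in theirs.non_tips():
                clade = frozenset(t.name for t in node.tips())
                side = all_leaves - clade if ref in clade else clade
                if 2 <= len(side) <= n - 2:
                    their_bips.add(side)
            assert ours.bipartitions() == their_bips

    def test_ultrametric_tie_break_deterministic(self):
        labels = ("a", "b", "c", "d")
        v = np.full((4, 4), 0.4)
        np.fill_diagonal(v, 0.0)
        t1 = neighbor_joining(_dm(v, labels))
        t2 = neighbor_joining(_dm(v, labels))
        assert t1.to_newick() == t2.to_newick()
        # documented rule joins the lexicographically first pair (a, b)
        assert t1.bipartitions() == {frozenset({"c", "d"})}

    def test_too_few_taxa_and_nan(self):
        with pytest.raises(TreeError):
            neighbor_joining(_dm([[0, 0.1], [0.1, 0]], "AB"))
        dm = _dm(np.zeros((3, 3)), "ABC")
        dm.values[0, 1] = dm.values[1, 0] = np.nan  # corrupt after validation
        with pytest.raises(TreeError):
            neighbor_joining(dm)


def _block_alignment(n_per_block=2, length=60):
    """Three deeply divergent, internally identical sequence blocks."""
    blocks = ["A" * length, "C" * length, "G" * 20 + "T" * 40]
    records = []
    for b, seq in enumerate(blocks):
        for i in range(n_per_block):
            records.append(
                AlignmentRecord(f"lib_b{b}s{i}", "lib", seq)
            )
    return Alignment(tuple(records), "dna")


class TestBootstrap:
    def test_congruent_blocks_full_support(self):
        aln = _block_alignment()
        tree = bootstrap_support(aln, n_replicates=30, seed=1)
        supports = [
            n.support
            for n in tree.root.traverse()
            if n.parent is not None and not n.is_leaf and n.support is not None
        ]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_supports_binary(self):
        aln = _block_alignment()
        tree = bootstrap_support(aln, n_replicates=1, seed=3)
        supports = [
            n.support
            for n in tree.root.traverse()
            if not n.is_leaf and n.parent is not None and n.support is not None
        ]
        assert set(supports) <= {0, 100}

    def test_seed_stability_within_binomial_bound(self):
        """Supports from two seeds differ by at most ~2 binomial s.e."""
        rng = np.random.default_rng(0)
        chars = np.array(list("ACGT"))
        # 10 moderately divergent sequences
        base = rng.integers(0, 4, size=200)
        records = []
        for i in range(10):
            seq = base.copy()
            sites = rng.choice(200, size=12 + 4 * i, replace=False)
            seq[sites] = (seq[sites] + rng.integers(1, 4, size=len(sites))) % 4
            records.append(
                AlignmentRecord(f"lib_s{i:02d}", "lib", "".join(chars[seq]))
            )
        aln = Alignment(tuple(records), "dna")
        n_rep = 300

        def support_map(seed):
            tree = bootstrap_support(aln, n_replicates=n_rep, seed=seed)
            out = {}
            all_leaves = frozenset(tree.leaf_names())
            ref = min(all_leaves)
            for node in tree.root.traverse():
                if node.parent is None or node.is_leaf or node.support is None:
                    continue
                clade = frozenset(n.name for n in node.traverse() if n.is_leaf)
                side = all_leaves - clade if ref in clade else clade
                out[side] = node.support
            return out

        s1, s2 = support_map(11), support_map(12)
        assert s1.keys() == s2.keys()
        # max binomial s.e. at p=0.5: sqrt(.25/300)*100 ~ 2.9 points
        for bp in s1:
            assert abs(s1[bp] - s2[bp]) <= 10

    def test_supports_invariant_to_leaf_order(self):
        aln = _block_alignment()
        tree1 = bootstrap_support(aln, n_replicates=25, seed=9)
        shuffled = Alignment(tuple(reversed(aln.records)), "dna")
        tree2 = bootstrap_support(shuffled, n_replicates=25, seed=9)
        assert tree1.bipartitions() == tree2.bipartitions()


class TestRooting:
    def test_three_taxon_outgroup_bipartition(self):
        dm = _dm([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], "ABC")
        rooted = root_with_outgroup(neighbor_joining(dm), "C")
        top = {
            frozenset(n.name for n in c.traverse() if n.is_leaf)
            for c in rooted.root.children
        }
        assert top == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_rooting_preserves_path_lengths(self, rng):
        labels, dist, _, _ = random_additive_tree(7, rng)
        tree = neighbor_joining(_dm(dist, labels))
        rooted = root_with_outgroup(tree, labels[3])
        p1, p2 = tree.leaf_path_lengths(), rooted.leaf_path_lengths()
        for k in p1:
            assert p2[k] == pytest.approx(p1[k], abs=1e-9)

    def test_root_then_unroot_is_topological_involution(self, rng):
        labels, dist, _, _ = random_additive_tree(6, rng)
        tree = neighbor_joining(_dm(dist, labels))
        rooted = root_with_outgroup(tree, labels[0])
        assert unroot(rooted).bipartitions() == tree.bipartitions()

    def test_unknown_outgroup(self, rng):
        labels, dist, _, _ = random_additive_tree(5, rng)
        tree = neighbor_joining(_dm(dist, labels))
        with pytest.raises(TreeError):
            root_with_outgroup(tree, "nope")

    def test_outgroup_pendant_edge_split_at_midpoint(self):
        dm = _dm([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], "ABC")
        rooted = root_with_outgroup(neighbor_joining(dm), "C")
        (c_child,) = [c for c in rooted.root.children if c.name == "C"]
        (other,) = [c for c in rooted.root.children if c.name != "C"]
        assert c_child.length == pytest.approx(0.125)
        assert other.length == pytest.approx(0.125)
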