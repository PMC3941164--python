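"""Shared fixtures and independent test helpers.

The helpers here (random additive trees, brute-force statistics) are
deliberately written without using the package's own implementations, so
they can serve as independent oracles.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from methanodiv.io import Alignment, AlignmentRecord


# ---------------------------------------------------------------------------
# independent random-additive-tree generator (never uses methanodiv.phylogeny)

class _SimpleNode:
    def __init__(self, name=None, length=0.0, children=()):
        self.name = name
        self.length = length
        self.children = list(children)

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary topology with positive branch lengths.

    Returns (labels, distance_matrix, bipartitions, path_lengths) where
    bipartitions are canonical frozensets (side without the first label)
    and path lengths come from explicit root-to-leaf traversal — an
    independent oracle for neighbor joining.
    """
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    nodes = [_SimpleNode(name=l, length=float(rng.uniform(0.05, 1.0))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[int(j)], nodes[int(i)]
        new = _SimpleNode(length=float(rng.uniform(0.05, 1.0)), children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(new)
    root = _SimpleNode(children=nodes)

    # leaf depths and clades by recursion
    depths: dict[str, float] = {}
    clades: list[frozenset] = []

    def walk(node, depth):
        if not node.children:
            depths[node.name] = depth + node.length
            return frozenset([node.name])
        clade = frozenset()
        for c in node.children:
            clade |= walk(c, depth + node.length)
        clades.append(clade)
        return clade

    for c in root.children:
        walk(c, 0.0)

    # pairwise path length via lowest common ancestor by explicit search
    def path_length(x, y):
        def find_path(node, target, acc):
            if not node.children:
                return acc + [node] if node.name == target else None
            for c in node.children:
                r = find_path(c, target, acc + [node])
                if r:
                    return r
            return None

        px = find_path(root, x, [])
        py = find_path(root, y, [])
        shared = 0
        for a, b in zip(px, py):
            if a is b:
                shared += 1
            else:
                break
        return sum(n.length for n in px[shared:]) + sum(
            n.length for n in py[shared:]
        )

    dist = np.zeros((n_taxa, n_taxa))
    paths = {}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d = path_length(labels[i], labels[j])
            dist[i, j] = dist[j, i] = d
            paths[frozenset((labels[i], labels[j]))] = d

    all_leaves = frozenset(labels)
    ref = min(all_leaves)
    bips = set()
    for clade in clades:
        side = all_leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n_taxa - 2:
            bips.add(side)
    return labels, dist, bips, paths


# ---------------------------------------------------------------------------
# brute-force diversity statistics (hand arithmetic, no numpy reductions)

def brute_shannon(counts):
    n = sum(counts)
    return -sum((c / n) * math.log(c / n) for c in counts)


def brute_chao1(counts):
    s = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return s + (f1 * f1 / (2 * f2) if f2 else f1 * (f1 - 1) / 2)


# ---------------------------------------------------------------------------
# small fixture alignments

@pytest.fixture
def toy_alignment():
    """Six 20-bp clones in two libraries; two exact-duplicate groups."""
    seqs = {
        "horse_c1": "ACGTACGTACGTACGTACGT",
        "horse_c2": "ACGTACGTACGTACGTACGT",
        "horse_c3": "ACGTACGTACGTACGTACGA",
        "pony_c1": "TTTTACGTACGTACGTACGT",
        "pony_c2": "TTTTACGTACGTACGTACGT",
        "pony_c3": "TTTTACGTACGTACGAACGT",
    }
    return Alignment(
        tuple(
            AlignmentRecord(k, k.split("_")[0], v) for k, v in seqs.items()
        ),
        "dna",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_distance_matrix(n, rng, low=0.0, high=1.0):
    """Random symmetric matrix with zero diagonal and distinct entries."""
    v = rng.uniform(low, high, size=(n, n))
    v = np.triu(v, k=1)
    v = v + v.T
    return v
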