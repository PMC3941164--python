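"""Neighbor-joining trees with nonparametric bootstrap support.

Trees are built from a distance matrix by the Saitou-Nei neighbor-joining
algorithm: at each step the pair (i, j) minimizing

    Q(i, j) = (m - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined, with branch lengths from the standard formulas. Negative branch
lengths are clamped to zero with the deficit transferred to the sister
branch (Kuhner-Felsenstein), preserving path lengths. The unrooted tree is
stored with a trifurcating root; an outgroup can be used to root it on the
outgroup's pendant edge.

Bootstrap support resamples alignment columns with replacement, rebuilds
the distance matrix and tree per replicate, and counts how often each
internal bipartition of the reference tree is recovered.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .distances import DistanceModel, distance_matrix
from .errors import IncomparablePairError, SaturationError, TreeError
from .io import Alignment, AlignmentRecord, DistanceMatrix


class TreeNode:
    """A node in a rooted representation of a (possibly unrooted) tree.

    ``length`` is the branch to the parent (None for the root), ``support``
    an optional integer bootstrap percentage on the edge above this node.
    """

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        for c in children or []:
            self.add_child(c)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.traverse()


class Tree:
    """A phylogenetic tree with labeled leaves and branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.bootstrap_skipped: int = 0
        self.bootstrap_replicates: int | None = None

    # -- queries ----------------------------------------------------------
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.traverse() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_edges(self) -> int:
        return sum(1 for n in self.root.traverse() if n.parent is not None)

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (internal edges only).

        Each split is represented by the leaf set on the side NOT containing
        the alphabetically first leaf, so the representation is independent
        of rooting.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.root.traverse():
            if node.parent is None or node.is_leaf:
                continue
            clade = frozenset(n.name for n in node.traverse() if n.is_leaf)
            side = all_leaves - clade if ref in clade else clade
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def leaf_path_lengths(self) -> dict[frozenset, float]:
        """Patristic distance between every pair of leaves."""
        dist_to_root: dict[int, float] = {}
        parent_of: dict[int, TreeNode] = {}
        for node in self.root.traverse():
            d = 0.0 if node.parent is None else (
                dist_to_root[id(node.parent)] + (node.length or 0.0)
            )
            dist_to_root[id(node)] = d
        leaves = self.leaves()

        def ancestors(n: TreeNode) -> list[TreeNode]:
            out = []
            while n is not None:
                out.append(n)
                n = n.parent
            return out

        result: dict[frozenset, float] = {}
        for i in range(len(leaves)):
            anc_i = ancestors(leaves[i])
            anc_i_ids = {id(a): a for a in anc_i}
            for j in range(i + 1, len(leaves)):
                n = leaves[j]
                while id(n) not in anc_i_ids:
                    n = n.parent
                lca = n
                result[frozenset((leaves[i].name, leaves[j].name))] = (
                    dist_to_root[id(leaves[i])]
                    + dist_to_root[id(leaves[j])]
                    - 2 * dist_to_root[id(lca)]
                )
        return result

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.support is not None:
                    s += str(int(node.support))
                elif node.name:
                    s += node.name
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"


def neighbor_joining(dmatrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; deterministic tie-breaking by label.

    Ties in the Q criterion are resolved toward the pair whose member
    clusters have the lexicographically smallest (min representative
    label, max representative label).
    """
    n = len(dmatrix)
    if n < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa, got {n}")
    if np.isnan(dmatrix.values).any():
        raise TreeError("distance matrix contains NaN")

    d = dmatrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dmatrix.labels]
    reps: list[str] = list(dmatrix.labels)  # min leaf label per cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # evaluate Q on the upper triangle only: floating-point addition
        # order would otherwise make q[i, j] != q[j, i] at the last ulp
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qv = q[iu]
        best = qv.min()
        pairs = [
            (int(iu[0][k]), int(iu[1][k]))
            for k in np.flatnonzero(qv == best)
        ]
        i, j = min(
            pairs,
            key=lambda ij: (
                min(reps[ij[0]], reps[ij[1]]),
                max(reps[ij[0]], reps[ij[1]]),
            ),
        )
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp-and-transfer keeps li + lj = dij
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        new = TreeNode(children=[a, b])
        new_dist = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_dist[keep]
        d_new[:-1, -1] = new_dist[keep]
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        d = d_new

    # final trifurcation
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(max(length, 0.0))
    root = TreeNode(children=list(nodes))
    return Tree(root)


def _resample_columns(alignment: Alignment, rng: np.random.Generator) -> Alignment:
    cols = rng.integers(0, alignment.length, size=alignment.length)
    records = tuple(
        AlignmentRecord(
            r.id, r.library, "".join(r.sequence[c] for c in cols)
        )
        for r in alignment.records
    )
    return Alignment(records, alignment.alphabet)


def bootstrap_support(
    alignment: Alignment,
    model: DistanceModel = DistanceModel(),
    n_replicates: int = 1000,
    seed: int = 0,
) -> Tree:
    """Reference NJ tree with bootstrap percentages on internal edges.

    Columns are resampled with replacement per replicate; replicates whose
    resampled alignment yields an incomparable or saturated pair are
    skipped and tallied in ``tree.bootstrap_skipped``. Supports are
    round(100 x recovery frequency) over successful replicates.
    """
    if n_replicates < 1:
        raise TreeError("need at least one bootstrap replicate")
    ref_tree = neighbor_joining(distance_matrix(alignment, model))
    counts: dict[frozenset, int] = {bp: 0 for bp in ref_tree.bipartitions()}
    rng = np.random.default_rng(seed)
    successes = 0
    skipped = 0
    for _ in range(n_replicates):
        resampled = _resample_columns(alignment, rng)
        try:
            rep_tree = neighbor_joining(distance_matrix(resampled, model))
        except (IncomparablePairError, SaturationError):
            skipped += 1
            continue
        successes += 1
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(ref_tree.leaf_names())
    ref_leaf = min(all_leaves)
    for node in ref_tree.root.traverse():
        if node.parent is None or node.is_leaf:
            continue
        clade = frozenset(n.name for n in node.traverse() if n.is_leaf)
        side = all_leaves - clade if ref_leaf in clade else clade
        if side in counts and successes > 0:
            node.support = int(round(100.0 * counts[side] / successes))
    ref_tree.bootstrap_skipped = skipped
    ref_tree.bootstrap_replicates = successes
    return ref_tree


def root_with_outgroup(tree: Tree, outgroup_label: str) -> Tree:
    """Root on the outgroup's pendant edge (split at its midpoint).

    Returns a new tree; the input is not modified. Path lengths between
    leaves are preserved exactly.
    """
    import copy

    work = copy.deepcopy(tree)
    outgroup = next(
        (n for n in work.root.traverse() if n.is_leaf and n.name == outgroup_label),
        None,
    )
    if outgroup is None:
        raise TreeError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    pendant = outgroup.length if outgroup.length is not None else 0.0
    old_parent = outgroup.parent
    old_parent.children.remove(outgroup)

    # reverse parent links from old_parent up to the old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    orig = [(n.length, n.support) for n in path]
    for k in range(len(path) - 1):
        child, parent = path[k], path[k + 1]
        parent.children.remove(child)
        child.add_child(parent)
        # the reversed edge keeps its own length/support, now stored on the
        # node that became the child
        parent.length, parent.support = orig[k]
    old_parent.length = pendant / 2.0
    old_parent.support = None
    old_parent.parent = None
    # collapse a degree-2 node left behind at the old root
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        only = old_root.children[0]
        grand = old_root.parent
        grand.children[grand.children.index(old_root)] = only
        only.parent = grand
        only.length = (only.length or 0.0) + (old_root.length or 0.0)
        if only.support is None:
            only.support = old_root.support

    outgroup.length = pendant / 2.0
    new_root = TreeNode(children=[outgroup, old_parent])
    return Tree(new_root)


def unroot(tree: Tree) -> Tree:
    """Collapse a bifurcating root into the trifurcating convention."""
    import copy

    work = copy.deepcopy(tree)
    root = work.root
    if len(root.children) != 2:
        return work
    a, b = root.children
    merged_length = (a.length or 0.0) + (b.length or 0.0)
    if b.is_leaf and not a.is_leaf:
        a, b = b, a
    if b.is_leaf:
        raise TreeError("cannot unroot a 2-leaf tree")
    # hang a off b's node, absorbing both root edges into one
    b.children.append(a)
    a.parent = b
    a.length = merged_length
    b.parent = None
    b.length = None
    return Tree(b)
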