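"""Distance-based trees, bootstrap support, and topology concordance.

Neighbor joining on Jukes–Cantor-corrected distances (negative branch
lengths are clamped to zero with the deficit moved to the sibling edge),
non-parametric bootstrap by column resampling, and counting of single-gene
trees whose induced topology contains each split of a reference
(concatenated-alignment) tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import skbio

from sagkit.divstats import jc_correct


class Node:
    """Minimal unrooted-tree node (rooted representation, trifurcating root)."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = length
        self.children = children or []

    def leaves(self):
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support=None) -> str:
        taxa = frozenset(self.leaves())
        anchor = min(taxa)

        def fmt(node):
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support is not None:
                side = frozenset(node.leaves())
                canonical = side if anchor not in side else taxa - side
                if canonical in with_support:
                    label = f"{with_support[canonical]:.0f}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


@dataclass
class SupportedTree:
    root: Node
    supports: dict = field(default_factory=dict)  # frozenset(bipartition side) -> percent
    labels: tuple = ()

    def newick(self) -> str:
        return self.root.newick(with_support=self.supports or None)


def jc_distance_matrix(alignment):
    """JC-corrected pairwise distances; errors on a saturated pair."""
    names = [n for n, _ in alignment]
    n = len(names)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        sa, sb = alignment[i][1], alignment[j][1]
        comparable = 0
        diffs = 0
        for a, b in zip(sa, sb):
            if a in "ACGT" and b in "ACGT":
                comparable += 1
                if a != b:
                    diffs += 1
        if comparable == 0:
            raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
        p = diffs / comparable
        d = jc_correct(p)
        if d is None:
            raise ValueError(
                f"saturated distance (p={p:.3f} >= 3/4) between {names[i]} and {names[j]}"
            )
        D[i, j] = D[j, i] = d
    return names, D


def neighbor_joining(names, D) -> Node:
    """Classic NJ; returns an unrooted tree with a trifurcating root.

    Negative branch-length estimates are clamped to zero and the deficit is
    moved to the sibling edge, preserving the path length between the two
    joined nodes.
    """
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name) for name in names]
    D = D.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = Node(children=[child_i, child_j])
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : -1] = new_row[:-1]
        D[: -1, -1] = new_row[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for node, ln in zip((nodes[i], nodes[j], nodes[k]), (li, lj, lk)):
        node.length = max(0.0, ln)
    return Node(children=[nodes[i], nodes[j], nodes[k]])


def tree_splits(root: Node):
    """Non-trivial bipartitions, each as the frozenset side not holding the
    lexicographically smallest leaf (canonical orientation)."""
    taxa = set(root.leaves())
    anchor = min(taxa)
    splits = set()

    def walk(node):
        if not node.children:
            return {node.name}
        below = set()
        for c in node.children:
            below |= walk(c)
        if 2 <= len(below) <= len(taxa) - 2:
            side = below if anchor not in below else taxa - below
            splits.add(frozenset(side))
        return below

    for c in root.children:
        walk(c)
    return splits


def build_tree(alignment) -> SupportedTree:
    """NJ tree from a multiple alignment via JC distances."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    names, D = jc_distance_matrix(alignment)
    root = neighbor_joining(names, D)
    return SupportedTree(root=root, labels=tuple(sorted(names)))


def bootstrap_support(alignment, reps: int = 100, seed: int = 0) -> SupportedTree:
    """Column-resampling bootstrap supports on the point-estimate NJ tree."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = build_tree(alignment)
    ref_splits = tree_splits(tree.root)
    length = len(alignment[0][1])
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in ref_splits}
    for _ in range(reps):
        cols = rng.integers(length, size=length)
        resampled = [(n, "".join(s[c] for c in cols)) for n, s in alignment]
        try:
            rep_tree = build_tree(resampled)
        except ValueError:  # saturated replicate
            continue
        rep_splits = tree_splits(rep_tree.root)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    tree.supports = {s: 100.0 * c / reps for s, c in counts.items()}
    return tree


def _restrict_split(side, taxa, common):
    """Project a bipartition onto a common taxon set, canonically oriented.

    Returns None when either restricted side has <2 taxa (not displayable).
    """
    a = frozenset(side) & common
    b = (frozenset(taxa) - frozenset(side)) & common
    if len(a) < 2 or len(b) < 2:
        return None
    anchor = min(common)
    return a if anchor not in a else b


def topology_concordance(gene_trees, reference: SupportedTree,
                         support_threshold: float = 80.0, warn=None):
    """Per-reference-split concordance counts across single-gene trees.

    For each non-trivial split of the reference tree, counts gene trees
    whose induced topology on the split's taxa contains it, and separately
    those where the gene tree's own bootstrap support for the split is
    >= ``support_threshold``.  Gene trees missing too many taxa to display
    a split are excluded from that split's denominator.  Returns a dict
    split -> dict(congruent, supported, testable, percent).
    """
    ref_taxa = set(reference.root.leaves())
    results = {}
    for split in sorted(tree_splits(reference.root), key=sorted):
        if len(split) < 2 or len(ref_taxa - split) < 2:
            if warn is not None:
                warn(f"split {sorted(split)} has <4 leaves; skipped")
            continue
        congruent = supported = testable = 0
        for gt in gene_trees:
            gt_taxa = set(gt.root.leaves())
            common = frozenset(gt_taxa & ref_taxa)
            target = _restrict_split(split, ref_taxa, common)
            if target is None:
                continue
            testable += 1
            gt_splits = {}
            for s in tree_splits(gt.root):
                rs = _restrict_split(s, gt_taxa, common)
                if rs is not None:
                    prev = gt_splits.get(rs, 0.0)
                    gt_splits[rs] = max(prev, gt.supports.get(s, 0.0))
            if target in gt_splits:
                congruent += 1
                if gt_splits[target] >= support_threshold:
                    supported += 1
        results[split] = {
            "congruent": congruent,
            "supported": supported,
            "testable": testable,
            "percent": 100.0 * congruent / testable if testable else float("nan"),
        }
    return results


def read_newick(source) -> SupportedTree:
    """Parse a newick string or file into a SupportedTree (no supports)."""
    if isinstance(source, str) and source.strip().endswith(";"):
        handle = io.StringIO(source)
    else:
        handle = str(source)
    sk = skbio.TreeNode.read(handle, format="newick")

    def convert(sknode):
        node = Node(name=sknode.name if sknode.is_tip() else None,
                    length=float(sknode.length or 0.0))
        node.children = [convert(c) for c in sknode.children]
        return node

    root = convert(sk)
    return SupportedTree(root=root, labels=tuple(sorted(root.leaves())))
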