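"""Robinson–Foulds symmetric difference between trees.

Both trees are reduced to their sets of non-trivial bipartitions (splits):
removing an internal edge partitions the leaves in two, and a split is kept
when both sides hold at least two leaves.  The distance is the size of the
symmetric difference of the two split sets — zero exactly for identical
unrooted topologies.  Branch lengths and rooting are ignored; splits are
canonicalized as the side *not* containing the lexicographically smallest
leaf label, so a rooted tree and its unrooted form compare equal.
"""

from __future__ import annotations

from .tree import PhyloTree, TreeNode

__all__ = ["tree_splits", "rf_distance", "max_rf"]


def tree_splits(t: PhyloTree) -> frozenset[frozenset[str]]:
    """Non-trivial splits of the (unrooted) tree, canonicalized.

    Each internal edge contributes the leaf set on its far side from the
    reference leaf (the lexicographically smallest label).  Multifurcations
    simply contribute fewer splits; duplicated splits induced by a rooted
    binary root collapse to one.
    """
    leaves = t.leaf_labels()
    if len(leaves) != len(set(leaves)):
        raise ValueError("tree has duplicate leaf labels")
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()

    def below(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])  # type: ignore[list-item]
        clade = frozenset().union(*(below(c) for c in node.children))
        # the edge above this node induces the split clade | rest
        side = all_leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            splits.add(side)
        return clade

    for child in t.root.children:
        below(child)
    return frozenset(splits)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson–Foulds) distance; 0 iff same topology."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise ValueError(
            "trees have different leaf sets; "
            f"only in first: {only1}, only in second: {only2}"
        )
    s1, s2 = tree_splits(t1), tree_splits(t2)
    return len(s1 ^ s2)


def max_rf(n_leaves: int) -> int:
    """Largest possible RF distance between two binary trees on n leaves."""
    return max(0, 2 * (n_leaves - 3))
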