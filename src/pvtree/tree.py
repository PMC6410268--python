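"""Phylogenetic trees: Newick I/O and Neighbor-Joining reconstruction.

The tree container is a plain rooted node structure; NJ output is an
unrooted tree represented with a trifurcating root (for n >= 3 taxa).
Saitou–Nei Neighbor Joining recovers additive (tree-like) distance
matrices exactly.  Negative branch-length estimates are clamped to zero
with the deficit moved onto the sibling edge, mirroring the behaviour of
the classic PHYLIP implementation, and ties in the Q-criterion are broken
on the lexicographically smallest active index pair so runs are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Optional

import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "neighbor_joining",
    "parse_newick",
    "to_newick",
    "read_newick",
    "write_newick",
    "leaf_path_lengths",
]

_NEWICK_META = set("(),:;'\t\n ")


@dataclass
class TreeNode:
    """A tree node; ``length`` is the edge to the parent (None = absent)."""

    label: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """A tree with labeled leaves; ``rooted`` records the interpretation."""

    root: TreeNode
    rooted: bool = False

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        labels = [n.label for n in self.leaves()]
        if any(l is None for l in labels):
            raise ValueError("tree has unlabeled leaves")
        return labels  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Neighbor Joining


def neighbor_joining(m: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ tree from a symmetric zero-diagonal distance matrix.

    On an additive matrix the leaf-to-leaf path lengths of the result equal
    the input distances exactly (up to floating point).  The result is
    unrooted; for n >= 3 the root trifurcates.
    """
    n = len(m.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    d = np.array(m.d, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode(
            children=[
                TreeNode(label=m.labels[0], length=half),
                TreeNode(label=m.labels[1], length=half),
            ]
        )
        return PhyloTree(root=root, rooted=False)

    nodes = [TreeNode(label=lbl) for lbl in m.labels]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_idx = n
    while len(active) > 3:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        nn = len(active)
        best = None
        best_q = np.inf
        for ii in range(nn):
            for jj in range(ii + 1, nn):
                i, j = active[ii], active[jj]
                q = (nn - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (nn - 2))
        lj = dij - li
        # clamp negatives, moving the deficit onto the sibling edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        nodes.append(parent)
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    # final trifurcation (or the 3-taxon star): x_i = (d_ij + d_ik - d_jk)/2
    i, j, k = active
    xi = (get(i, j) + get(i, k) - get(j, k)) / 2.0
    xj = (get(i, j) + get(j, k) - get(i, k)) / 2.0
    xk = (get(i, k) + get(j, k) - get(i, j)) / 2.0
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    for node, x in ((nodes[i], xi), (nodes[j], xj), (nodes[k], xk)):
        node.length = max(x, 0.0)
    return PhyloTree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# Newick


def _quote_label(label: str) -> str:
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf:
        s = _quote_label(node.label or "")
    else:
        s = "(" + ",".join(_node_newick(c) for c in node.children) + ")"
        if node.label:
            s += _quote_label(node.label)
    if node.length is not None:
        s += ":" + _format_length(node.length)
    return s


def to_newick(t: PhyloTree) -> str:
    """Serialize with branch lengths; labels with metacharacters quoted."""
    return _node_newick(t.root) + ";"


class _NewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> ValueError:
        return ValueError(f"Newick parse error at position {self.pos}: {msg}")

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\n\r":
            self.pos += 1

    def parse(self) -> TreeNode:
        node = self.parse_node()
        if self.peek() != ";":
            raise self.error("expected ';'")
        self.pos += 1
        self._skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing characters after ';'")
        return node

    def parse_node(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            node.children.append(self.parse_node())
            while self.peek() == ",":
                self.pos += 1
                node.children.append(self.parse_node())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.pos += 1
        label = self.parse_label()
        if label:
            node.label = label
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        return node

    def parse_label(self) -> str:
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label")
                c = self.text[self.pos]
                if c == "'":
                    if self.text[self.pos : self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(c)
                self.pos += 1
            return "".join(out)
        out = []
        while self.pos < len(self.text) and self.text[self.pos] not in "(),:;'":
            out.append(self.text[self.pos])
            self.pos += 1
        return "".join(out).strip()

    def parse_number(self) -> float:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isdigit()
            or self.text[self.pos] in "+-.eE"
        ):
            self.pos += 1
        if start == self.pos:
            raise self.error("expected branch length")
        try:
            return float(self.text[start : self.pos])
        except ValueError:
            raise self.error(
                f"bad branch length {self.text[start:self.pos]!r}"
            ) from None


def parse_newick(s: str) -> PhyloTree:
    """Parse a single Newick tree; errors report the offending position."""
    if not s.strip():
        raise ValueError("Newick parse error at position 0: empty input")
    root = _NewickParser(s.strip()).parse()
    rooted = len(root.children) == 2
    return PhyloTree(root=root, rooted=rooted)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(t: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(t) + "\n")


# ---------------------------------------------------------------------------
# path lengths (additivity checks)


def leaf_path_lengths(t: PhyloTree) -> dict[tuple[str, str], float]:
    """Patristic distance for every unordered leaf pair.

    Edges without a stored length count as zero.
    """
    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            below = {node.label or "": 0.0}
        else:
            below = {}
            sub = [collect(c) for c in node.children]
            for a, b in combinations(range(len(sub)), 2):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        key = (la, lb) if la < lb else (lb, la)
                        pairs[key] = da + db
            for s in sub:
                below.update(s)
        edge = node.length or 0.0
        return {l: d + edge for l, d in below.items()}

    pairs: dict[tuple[str, str], float] = {}
    collect(t.root)
    return pairs
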