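"""Tree-guided sequence-family simulator for end-to-end validation.

A root sequence is evolved along a random guide tree: on a branch of
length t each site substitutes with probability 1 - exp(-r t) to a
uniformly chosen different residue, and insertion/deletion events arrive
as a per-site Poisson process with geometrically distributed lengths.
The guide tree is the true history, so topology recovery by the pipeline
can be scored with the Robinson–Foulds distance and no external simulator
or download is needed.

The substitution model is deliberately simple (uniform exchangeabilities,
no site heterogeneity): the reconstruction pipeline consumes sequences,
not the mutation process, so a single divergence dial — the substitution
rate, optionally plus indel rates — suffices for validation.  Divergence
is reported as mean pairwise percent identity of the simulated leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional

import edlib
import numpy as np

from .seq_io import Alphabet, SequenceRecord, SequenceSet
from .tree import PhyloTree, TreeNode

__all__ = [
    "EvolutionParams",
    "SimulationResult",
    "random_tree",
    "evolve",
    "simulate_family",
    "mean_pairwise_identity",
]

_RESIDUES = {
    Alphabet.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
    Alphabet.DNA: "ACGT",
    Alphabet.RNA: "ACGU",
}


@dataclass(frozen=True)
class EvolutionParams:
    """Rates and sizes of the simulation.

    All rates are per site per unit branch length.  ``indel_mean_length``
    is the mean of the geometric length distribution shared by insertions
    and deletions.
    """

    root_length: int = 350
    substitution_rate: float = 0.22
    insertion_rate: float = 0.05
    deletion_rate: float = 0.02
    indel_mean_length: float = 2.0
    alphabet: Alphabet = Alphabet.PROTEIN
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.indel_mean_length < 1:
            raise ValueError("indel_mean_length must be >= 1")


@dataclass
class SimulationResult:
    """Leaves plus the guide tree that generated them."""

    guide_tree: PhyloTree
    leaves: SequenceSet
    params: EvolutionParams


def random_tree(
    n_leaves: int,
    seed: int,
    branch_length_range: tuple[float, float] = (0.2, 0.25),
) -> PhyloTree:
    """Random binary tree by successive random leaf attachment (Yule).

    Each new leaf splits a uniformly chosen *leaf* edge — the Yule pure-
    birth process, which yields realistically balanced topologies.  Every
    edge of the final tree then receives an independent uniform length
    from ``branch_length_range``; internal edges are never shorter than
    the interval's lower bound (arbitrarily short internal edges would
    make topologies unrecoverable by *any* method).  Deterministic for a
    given seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    lo, hi = branch_length_range
    if not (0 < lo <= hi):
        raise ValueError("branch length range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)

    width = len(str(n_leaves))
    labels = [f"t{i + 1:0{width}d}" for i in range(n_leaves)]
    root = TreeNode(
        children=[TreeNode(label=labels[0]), TreeNode(label=labels[1])]
    )
    # pending leaf edges as (parent, child-index) pairs
    leaf_edges: list[tuple[TreeNode, int]] = [(root, 0), (root, 1)]
    for label in labels[2:]:
        idx = int(rng.integers(len(leaf_edges)))
        parent, ci = leaf_edges[idx]
        child = parent.children[ci]
        mid = TreeNode(children=[child, TreeNode(label=label)])
        parent.children[ci] = mid
        leaf_edges[idx] = (mid, 0)
        leaf_edges.append((mid, 1))
    for node in root.walk():
        if node is not root:
            node.length = float(rng.uniform(lo, hi))
    return PhyloTree(root=root, rooted=True)


def _evolve_branch(
    seq: np.ndarray,
    t: float,
    params: EvolutionParams,
    rng: np.random.Generator,
    n_residues: int,
) -> np.ndarray:
    if t <= 0:
        return seq.copy()
    seq = seq.copy()
    L = len(seq)
    # substitutions: jump to a uniformly chosen *different* residue
    p_sub = 1.0 - np.exp(-params.substitution_rate * t)
    mask = rng.random(L) < p_sub
    k = int(mask.sum())
    if k:
        shift = rng.integers(1, n_residues, size=k)
        seq[mask] = (seq[mask] + shift) % n_residues
    # deletions
    n_del = rng.poisson(params.deletion_rate * t * len(seq))
    for _ in range(n_del):
        if len(seq) <= 1:
            break
        length = int(rng.geometric(1.0 / params.indel_mean_length))
        start = int(rng.integers(len(seq)))
        seq = np.delete(seq, slice(start, min(start + length, len(seq))))
        if len(seq) == 0:
            seq = rng.integers(n_residues, size=1)
    # insertions of random residues
    n_ins = rng.poisson(params.insertion_rate * t * len(seq))
    for _ in range(n_ins):
        length = int(rng.geometric(1.0 / params.indel_mean_length))
        pos = int(rng.integers(len(seq) + 1))
        seq = np.insert(seq, pos, rng.integers(n_residues, size=length))
    return seq


def evolve(tree: PhyloTree, params: EvolutionParams) -> SimulationResult:
    """Evolve a uniform random root along ``tree``; leaves keep tree labels."""
    residues = _RESIDUES[params.alphabet]
    n_res = len(residues)
    rng = np.random.default_rng(params.seed)
    root_seq = rng.integers(n_res, size=params.root_length)
    records: list[SequenceRecord] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve_branch(
                seq, child.length or 0.0, params, rng, n_res
            )
            if child.is_leaf:
                records.append(
                    SequenceRecord(
                        id=child.label or "",
                        residues="".join(residues[i] for i in child_seq),
                    )
                )
            else:
                descend(child, child_seq)

    descend(tree.root, root_seq)
    leaves = SequenceSet(records=records, alphabet=params.alphabet)
    return SimulationResult(guide_tree=tree, leaves=leaves, params=params)


def simulate_family(
    n_leaves: int,
    params: Optional[EvolutionParams] = None,
    seed: Optional[int] = None,
    branch_length_range: tuple[float, float] = (0.2, 0.25),
) -> SimulationResult:
    """Random guide tree plus evolved leaves in one call."""
    params = params or EvolutionParams()
    if seed is not None:
        params = replace(params, seed=seed)
    tree = random_tree(
        n_leaves, seed=params.seed, branch_length_range=branch_length_range
    )
    return evolve(tree, params)


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the global (Needleman–Wunsch) alignment of two strings.

    Computed as 1 - edit_distance / max(len), i.e. matches over the longer
    sequence; in [0, 1].
    """
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def mean_pairwise_identity(seqs: SequenceSet) -> float:
    """Mean of :func:`pairwise_identity` over all unordered pairs."""
    pairs = list(combinations([r.residues for r in seqs], 2))
    if not pairs:
        raise ValueError("need at least two sequences")
    return float(np.mean([pairwise_identity(a, b) for a, b in pairs]))
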