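"""Jensen–Shannon distances between normalized pattern vectors.

Pattern vectors are normalized to probability vectors (entries divided by
the vector sum) and compared with the Jensen–Shannon divergence

    JS(P, Q) = 1/2 KL(P, M) + 1/2 KL(Q, M),   M = (P + Q) / 2

with Kullback–Leibler divergence in log base 2, which bounds JS to [0, 1].
The matrix stores JS itself; its square root (a metric) is available behind
a flag.  An all-zero vector has no distribution; by convention its distance
to any non-zero vector is 1 (maximal) and to another all-zero vector 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .vectorize import PatternVector

__all__ = [
    "ProbabilityVector",
    "DistanceMatrix",
    "normalize",
    "kl_divergence",
    "js_distance",
    "distance_matrix",
    "write_phylip",
    "write_tsv",
    "read_phylip",
]

_SUM_TOL = 1e-9


@dataclass
class ProbabilityVector:
    """A normalized vector; ``is_zero`` flags the degenerate all-zero case."""

    values: np.ndarray
    is_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.is_zero and abs(self.values.sum() - 1.0) > _SUM_TOL:
            raise ValueError("probability vector entries must sum to 1")

    def __len__(self) -> int:
        return len(self.values)


def normalize(v: Union[PatternVector, Sequence[float], np.ndarray]) -> ProbabilityVector:
    """Divide by the entry sum; an all-zero input is returned flagged."""
    values = np.asarray(v.values if isinstance(v, PatternVector) else v, dtype=float)
    if np.any(values < 0):
        raise ValueError("pattern vector entries must be non-negative")
    total = values.sum()
    if total == 0:
        return ProbabilityVector(values=np.zeros_like(values), is_zero=True)
    return ProbabilityVector(values=values / total)


def kl_divergence(p: ProbabilityVector, m: ProbabilityVector) -> float:
    """``sum_i p_i log2(p_i / m_i)`` with the 0 log 0 terms dropped."""
    pv, mv = p.values, m.values
    if len(pv) != len(mv):
        raise ValueError("vector length mismatch")
    mask = pv > 0
    if np.any(mv[mask] == 0):
        raise ValueError("KL undefined: p > 0 where m = 0")
    return float(np.sum(pv[mask] * np.log2(pv[mask] / mv[mask])))


def js_distance(
    p: ProbabilityVector, q: ProbabilityVector, sqrt: bool = False
) -> float:
    """Jensen–Shannon divergence of two probability vectors, in [0, 1].

    ``sqrt=True`` returns the square root, which satisfies the triangle
    inequality.  Degenerate all-zero operands: one flagged -> 1.0, both ->
    0.0.
    """
    if len(p) != len(q):
        raise ValueError("vector length mismatch")
    if p.is_zero or q.is_zero:
        d = 0.0 if (p.is_zero and q.is_zero) else 1.0
        return float(np.sqrt(d)) if sqrt else d
    m = ProbabilityVector(values=(p.values + q.values) / 2.0)
    d = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    d = min(max(d, 0.0), 1.0)  # clip floating-point spill at the bounds
    return float(np.sqrt(d)) if sqrt else d


@dataclass
class DistanceMatrix:
    """Symmetric labeled matrix of pairwise distances in [0, 1]."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if np.any(np.isnan(self.d)):
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def distance_matrix(
    vectors: list[PatternVector], sqrt: bool = False
) -> DistanceMatrix:
    """Pairwise JS distances over normalized vectors, labels in input order."""
    if len(vectors) < 2:
        raise ValueError("need at least two vectors for a distance matrix")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("vectors must share one feature space")
    probs = [normalize(v) for v in vectors]
    if any(p.is_zero for p in probs):
        warnings.warn(
            "all-zero pattern vector(s) present; their distances use the "
            "degenerate convention (1.0 to any non-zero vector)",
            stacklevel=2,
        )
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = js_distance(probs[i], probs[j], sqrt=sqrt)
    return DistanceMatrix(labels=[v.sequence_id for v in vectors], d=d)


# ---------------------------------------------------------------------------
# serialization


def _phylip_name(label: str) -> str:
    # classic PHYLIP fixed-width name field
    return label[:10].ljust(10)


def write_phylip(m: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(m)}\n")
        for label, row in zip(m.labels, m.d):
            vals = "  ".join(f"{v:.6f}" for v in row)
            fh.write(f"{_phylip_name(label)}  {vals}\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (whitespace separated)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"empty distance-matrix file: {path}")
    n = int(tokens[0])
    if len(tokens) != 1 + n * (n + 1):
        raise ValueError(f"malformed PHYLIP matrix in {path}")
    labels, rows = [], []
    pos = 1
    for _ in range(n):
        labels.append(tokens[pos])
        rows.append([float(t) for t in tokens[pos + 1 : pos + 1 + n]])
        pos += 1 + n
    return DistanceMatrix(labels=labels, d=np.array(rows))


def write_tsv(m: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.d):
            vals = "\t".join(f"{v:.10g}" for v in row)
            fh.write(f"{label}\t{vals}\n")
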