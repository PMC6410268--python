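"""Pattern feature space and per-sequence pattern vectors.

Each closed pattern receives an IDF-like weight

    W = PatLength * log2(DBSize / PatSup)

so longer and rarer patterns count more, and a pattern present in every
sequence is non-discriminative (weight 0).  A sequence's vector holds, per
pattern, either membership (binary mode) or the weight itself (weighted
mode); within-sequence multiplicity is ignored because support is defined
at the sequence level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .mining import Pattern, PatternSetResult
from .seq_io import SequenceSet

__all__ = [
    "FeatureSpace",
    "PatternVector",
    "pattern_weight",
    "build_feature_space",
    "vectorize_sequences",
    "write_vectors_tsv",
]


def pattern_weight(pat_length: int, db_size: int, pat_sup: int) -> float:
    """Weight of one pattern: ``pat_length * log2(db_size / pat_sup)``.

    ``pat_length`` counts wildcards; ``pat_sup`` is the absolute support.
    Zero exactly when the pattern occurs in every sequence.
    """
    if pat_sup < 1:
        raise ValueError(f"pattern support must be >= 1, got {pat_sup}")
    if pat_sup > db_size:
        raise ValueError(
            f"pattern support {pat_sup} exceeds database size {db_size}"
        )
    if pat_length < 1:
        raise ValueError("pattern length must be >= 1")
    return pat_length * math.log2(db_size / pat_sup)


@dataclass
class FeatureSpace:
    """Ordered closed patterns with their weights — the vector coordinates."""

    patterns: list[Pattern]
    weights: np.ndarray
    db_size: int

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def pattern_strings(self) -> list[str]:
        return [p.string for p in self.patterns]


@dataclass
class PatternVector:
    """One sequence's coordinates in a :class:`FeatureSpace`."""

    sequence_id: str
    values: np.ndarray
    mode: str = "weighted"

    def __len__(self) -> int:
        return len(self.values)


def build_feature_space(result: PatternSetResult) -> FeatureSpace:
    """Compute weights for a mining result, preserving its pattern order."""
    if len(result.patterns) == 0:
        warnings.warn("empty mining result yields an empty feature space",
                      stacklevel=2)
        return FeatureSpace(patterns=[], weights=np.zeros(0), db_size=result.db_size)
    weights = np.array(
        [
            pattern_weight(p.length, result.db_size, p.support_count)
            for p in result.patterns
        ]
    )
    return FeatureSpace(
        patterns=list(result.patterns), weights=weights, db_size=result.db_size
    )


def vectorize_sequences(
    seqs: SequenceSet,
    space: FeatureSpace,
    mode: str = "weighted",
) -> list[PatternVector]:
    """One vector per input sequence, in input order.

    Membership is decided by scanning each sequence against each pattern
    (not via the mining-time supporting ids), so held-out sequences can be
    projected into an existing feature space.  ``mode`` is ``"binary"``
    (entries 0/1) or ``"weighted"`` (entries 0/W).
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown vector mode: {mode!r}")
    regexes = [p.regex() for p in space.patterns]
    out: list[PatternVector] = []
    for rec in seqs:
        member = np.array(
            [1.0 if rx.search(rec.residues) else 0.0 for rx in regexes]
        )
        values = member if mode == "binary" else member * space.weights
        if len(member) and not member.any():
            warnings.warn(
                f"sequence {rec.id!r} matches no pattern; its vector is all "
                "zero",
                stacklevel=2,
            )
        out.append(PatternVector(sequence_id=rec.id, values=values, mode=mode))
    return out


def write_vectors_tsv(
    vectors: list[PatternVector], space: FeatureSpace, path
) -> None:
    """Matrix TSV: rows = sequence ids, columns = pattern strings."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(space.pattern_strings) + "\n")
        for vec in vectors:
            vals = "\t".join(f"{v:.10g}" for v in vec.values)
            fh.write(f"{vec.sequence_id}\t{vals}\n")
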