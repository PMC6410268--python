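"""FASTA input/output and the in-memory sequence database.

Sequences are the mining database for pattern discovery: the method is
alignment-free, so gap characters (``-`` and ``.``) are always stripped on
input, and residues are uppercased.  The record count of a
:class:`SequenceSet` (``db_size``) is the DBSize term of the pattern
weighting formula.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "SequenceSet",
    "read_fasta",
    "write_fasta",
]

_GAP_CHARS = "-."

# Ambiguity codes (B, Z, J, X, U, O) are kept as ordinary residues: the
# mining wildcard is an internal sentinel, never a residue character, so an
# input 'X' matches only itself or a wildcard.
_PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY" "BJOUXZ*")
_DNA_LETTERS = frozenset("ACGTN")
_RNA_LETTERS = frozenset("ACGUN")
_NUCLEOTIDE_LETTERS = frozenset("ACGTUN")


class Alphabet(str, Enum):
    """Residue alphabet of a sequence set."""

    PROTEIN = "protein"
    DNA = "dna"
    RNA = "rna"

    @property
    def letters(self) -> frozenset[str]:
        return {
            Alphabet.PROTEIN: _PROTEIN_LETTERS,
            Alphabet.DNA: _DNA_LETTERS,
            Alphabet.RNA: _RNA_LETTERS,
        }[self]


@dataclass(frozen=True)
class SequenceRecord:
    """One sanitized sequence: unique id, uppercased gap-free residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of records over one alphabet.

    ``db_size`` is the number of records and enters the pattern weight as
    DBSize.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    alphabet: Alphabet = Alphabet.PROTEIN

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
        letters = self.alphabet.letters
        for rec in self.records:
            bad = set(rec.residues) - letters
            if bad:
                raise ValueError(
                    f"sequence {rec.id!r} contains characters outside the "
                    f"{self.alphabet.value} alphabet: {sorted(bad)}"
                )

    @property
    def db_size(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: Union[int, str]) -> SequenceRecord:
        if isinstance(key, int):
            return self.records[key]
        for rec in self.records:
            if rec.id == key:
                return rec
        raise KeyError(key)

    def as_dict(self) -> dict[str, str]:
        """Map of id -> residues, in record order."""
        return {rec.id: rec.residues for rec in self.records}


def _sanitize(raw: str) -> str:
    s = raw.upper()
    for g in _GAP_CHARS:
        s = s.replace(g, "")
    return s


def _detect_alphabet(seqs: Iterable[str]) -> Alphabet:
    letters: set[str] = set()
    for s in seqs:
        letters.update(s)
    if letters <= _NUCLEOTIDE_LETTERS:
        return Alphabet.RNA if "U" in letters else Alphabet.DNA
    return Alphabet.PROTEIN


def read_fasta(
    path: Union[str, Path],
    alphabet: Union[Alphabet, str] = "auto",
) -> SequenceSet:
    """Read a (optionally gzipped) FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased and gap characters stripped; ids must be unique
    and every residue must belong to the declared (or auto-detected)
    alphabet.  An empty file is an error.
    """
    path = Path(path)
    if str(path).endswith(".gz"):
        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    with handle:
        raw = [
            (rec.id, _sanitize(str(rec.seq)), rec.description)
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not raw:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r[0] for r in raw]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sequence id: {sorted(dupes)[0]!r}")
    if alphabet == "auto":
        alpha = _detect_alphabet(r[1] for r in raw)
    else:
        alpha = Alphabet(alphabet)
    records = [
        SequenceRecord(id=i, residues=s, description=d) for i, s, d in raw
    ]
    return SequenceSet(records=records, alphabet=alpha)


def write_fasta(
    seqs: SequenceSet, path: Union[str, Path], width: int = 60
) -> None:
    """Write the set as FASTA, wrapped at ``width`` columns."""
    bio = [
        _BioRecord(Seq(rec.residues), id=rec.id, description=rec.description)
        for rec in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
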