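"""Closed frequent sequential pattern mining with single-residue wildcards.

A pattern is an ordered string over the residue alphabet interleaved with a
wildcard symbol that matches exactly one arbitrary residue; it matches a
sequence contiguously.  Support counts the number of distinct sequences
containing at least one occurrence.  Only *closed* patterns are reported: a
frequent pattern is discarded when some admissible proper super-pattern
(left/right extension or wildcard-to-residue specialization) has identical
support, because such a pattern carries no information its super-pattern
does not.

The miner grows patterns depth-first over projected databases: for the
current pattern each supporting sequence stores the end positions of all its
occurrences, so appending one item only needs a single-character look-ahead
per occurrence.  Two prunes keep the search tractable:

* support prune — a branch whose projection supports fewer sequences than
  the threshold can never recover (support is anti-monotone);
* wildcard subsumption — when the wildcard extension's projection equals
  some residue extension's projection position-for-position, every pattern
  in the wildcard subtree specializes to an equal-support pattern in the
  residue subtree, hence none is closed and the subtree is skipped.

Admissibility constraints: both terminal items are residues, no run of more
than ``max_wc`` consecutive wildcards, and at least ``min_non_wc`` residue
items.  Closedness is evaluated within this constrained pattern space.

``enumerate_patterns_bruteforce`` is an independent oracle for tiny inputs:
it enumerates candidate strings directly, counts support by regular
expression scanning, and decides closedness by pairwise containment — no
projected databases involved.
"""

from __future__ import annotations

import math
import re
import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .seq_io import SequenceSet

__all__ = [
    "WILDCARD",
    "Pattern",
    "MiningParams",
    "ProjectedDatabase",
    "PatternSetResult",
    "mine_closed_patterns",
    "grow",
    "is_closed",
    "enumerate_patterns_bruteforce",
    "write_patterns_tsv",
]

#: Internal wildcard sentinel; deliberately not a printable residue letter so
#: that the amino-acid ambiguity code 'X' stays an ordinary residue.
WILDCARD = "\x00"

#: Character used when rendering patterns as text (regex-style single char).
WILDCARD_CHAR = "."

# Sort key: wildcard orders after every residue letter.
_SORT_WC = "\x7f"


def _render(items: Iterable[str], wildcard_char: str = WILDCARD_CHAR) -> str:
    return "".join(wildcard_char if c == WILDCARD else c for c in items)


def _parse_items(text: str, wildcard_char: str = WILDCARD_CHAR) -> tuple[str, ...]:
    return tuple(WILDCARD if c == wildcard_char else c for c in text)


def _sort_key(items: tuple[str, ...]) -> str:
    return "".join(_SORT_WC if c == WILDCARD else c for c in items)


@dataclass(frozen=True)
class Pattern:
    """A mined pattern with its support.

    ``items`` mixes residue characters and the :data:`WILDCARD` sentinel;
    ``length`` (the PatLength of the weighting formula) counts wildcards,
    ``non_wc`` does not.  ``support_count`` (PatSup) is the number of
    distinct supporting sequences.
    """

    items: tuple[str, ...]
    support_count: int = 0
    supporting_ids: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return len(self.items)

    @property
    def non_wc(self) -> int:
        return sum(1 for c in self.items if c != WILDCARD)

    @property
    def string(self) -> str:
        """Pattern rendered with '.' for the wildcard."""
        return _render(self.items)

    @classmethod
    def from_string(
        cls,
        text: str,
        support_count: int = 0,
        supporting_ids: Iterable[str] = (),
        wildcard_char: str = WILDCARD_CHAR,
    ) -> "Pattern":
        return cls(
            items=_parse_items(text, wildcard_char),
            support_count=support_count,
            supporting_ids=frozenset(supporting_ids),
        )

    def regex(self) -> "re.Pattern[str]":
        """Compiled regex matching one occurrence (wildcard = any residue)."""
        return re.compile(
            "".join("." if c == WILDCARD else re.escape(c) for c in self.items)
        )

    def occurrence_ends(self, sequence: str) -> frozenset[int]:
        """0-based positions just past each (possibly overlapping) match."""
        rx = re.compile("(?=(" + self.regex().pattern + "))")
        L = len(self.items)
        return frozenset(m.start() + L for m in rx.finditer(sequence))

    def __str__(self) -> str:
        return self.string


@dataclass(frozen=True)
class MiningParams:
    """Mining thresholds.

    ``min_support`` is either a fraction of the database in (0, 1] or an
    absolute sequence count; a fraction f resolves to
    ``max(2, ceil(f * db_size))`` — patterns private to a single sequence
    carry no phylogenetic signal, hence the floor of 2.  ``min_non_wc`` is
    the minimum number of residue (non-wildcard) items per reported pattern
    and ``max_wc`` the longest allowed run of consecutive wildcards.
    """

    min_support: Union[int, float] = 0.03
    min_non_wc: int = 2
    max_wc: int = 2

    def __post_init__(self) -> None:
        ms = self.min_support
        if isinstance(ms, bool) or ms <= 0:
            raise ValueError("min_support must be positive")
        if isinstance(ms, float) and not ms.is_integer() and ms > 1:
            raise ValueError("fractional min_support must lie in (0, 1]")
        if self.min_non_wc < 1:
            raise ValueError("min_non_wc must be >= 1")
        if self.max_wc < 0:
            raise ValueError("max_wc must be >= 0")

    def resolve_support(self, db_size: int) -> int:
        """Absolute support threshold for a database of ``db_size`` records."""
        ms = self.min_support
        if isinstance(ms, float) and 0 < ms <= 1:
            return max(2, math.ceil(ms * db_size))
        return int(ms)


@dataclass
class ProjectedDatabase:
    """Occurrence end positions of one pattern, per supporting sequence.

    ``ends[sid]`` holds the 0-based index just past the last matched item of
    every occurrence in sequence ``sid``; sequences without occurrences are
    absent.  ``support`` is therefore the number of keys.
    """

    sequences: Mapping[str, str]
    ends: dict[str, frozenset[int]] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.ends)

    @property
    def supporting_ids(self) -> frozenset[str]:
        return frozenset(self.ends)


@dataclass
class PatternSetResult:
    """The closed-pattern set together with the parameters that produced it."""

    patterns: list[Pattern]
    params: MiningParams
    db_size: int

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def as_dict(self) -> dict[str, int]:
        """Map rendered pattern string -> support count."""
        return {p.string: p.support_count for p in self.patterns}


# ---------------------------------------------------------------------------
# projected-database growth


def grow(
    pattern: Pattern,
    pdb: ProjectedDatabase,
    item: str,
) -> tuple[Pattern, ProjectedDatabase]:
    """Append ``item`` (a residue or :data:`WILDCARD`) to ``pattern``.

    Every occurrence advances by one position where the appended item
    matches the next character (the wildcard matches any residue);
    sequences left without occurrences drop out, so support can only
    shrink.
    """
    new_ends: dict[str, frozenset[int]] = {}
    for sid, ends in pdb.ends.items():
        seq = pdb.sequences[sid]
        n = len(seq)
        if item == WILDCARD:
            adv = frozenset(e + 1 for e in ends if e < n)
        else:
            adv = frozenset(e + 1 for e in ends if e < n and seq[e] == item)
        if adv:
            new_ends[sid] = adv
    new_pdb = ProjectedDatabase(sequences=pdb.sequences, ends=new_ends)
    new_pattern = Pattern(
        items=pattern.items + (item,),
        support_count=new_pdb.support,
        supporting_ids=new_pdb.supporting_ids,
    )
    return new_pattern, new_pdb


def _closed_from_occurrences(
    items: tuple[str, ...],
    ends: Mapping[str, frozenset[int]],
    sequences: Mapping[str, str],
    max_wc: int,
) -> bool:
    """Closedness test from the pattern's own occurrence positions.

    The pattern is non-closed iff some admissible one-chunk super-pattern —
    a right or left extension by k<=max_wc wildcards plus one residue, or a
    wildcard specialized to a residue — is supported by *every* supporting
    sequence (support can never grow, so 'every' means equal support).  Any
    equal-support super-pattern is reachable through a chain of such chunks
    with support constant along the chain, so one-chunk checks are complete.
    """
    L = len(items)
    # right extensions: residue at offset k past an occurrence end
    for k in range(max_wc + 1):
        inter: Optional[set[str]] = None
        for sid, eset in ends.items():
            seq = sequences[sid]
            n = len(seq)
            chars = {seq[e + k] for e in eset if e + k < n}
            inter = chars if inter is None else inter & chars
            if not inter:
                break
        if inter:
            return False
    # left extensions: residue at offset k+1 before an occurrence start
    for k in range(max_wc + 1):
        inter = None
        for sid, eset in ends.items():
            seq = sequences[sid]
            chars = {
                seq[e - L - k - 1] for e in eset if e - L - k - 1 >= 0
            }
            inter = chars if inter is None else inter & chars
            if not inter:
                break
        if inter:
            return False
    # wildcard specialization: same residue under a wildcard everywhere
    for i, item in enumerate(items):
        if item != WILDCARD:
            continue
        inter = None
        for sid, eset in ends.items():
            seq = sequences[sid]
            chars = {seq[e - L + i] for e in eset}
            inter = chars if inter is None else inter & chars
            if not inter:
                break
        if inter:
            return False
    return True


def is_closed(
    pattern: Pattern, seqs: SequenceSet, params: MiningParams
) -> bool:
    """True iff no admissible proper super-pattern has equal support.

    Super-patterns considered: extensions on either end and replacement of a
    wildcard by a residue, all respecting ``max_wc`` and the
    residue-terminal rule.  Occurrences are recomputed by direct scanning,
    so the pattern need not originate from this module's miner.
    """
    sequences = seqs.as_dict()
    ends = {
        sid: occ
        for sid, res in sequences.items()
        if (occ := pattern.occurrence_ends(res))
    }
    if not ends:
        raise ValueError(f"pattern {pattern.string!r} does not occur in the set")
    return _closed_from_occurrences(
        pattern.items, ends, sequences, params.max_wc
    )


def mine_closed_patterns(
    seqs: SequenceSet, params: Optional[MiningParams] = None
) -> PatternSetResult:
    """Mine all closed frequent patterns from a sequence set.

    Depth-first pattern growth over projected databases; see the module
    docstring for the search-space constraints and prunes.  Output is
    deterministic: patterns sort lexicographically with the wildcard
    ordering after every residue.
    """
    params = params or MiningParams()
    if len(seqs) == 0:
        raise ValueError("cannot mine an empty sequence set")
    sequences = seqs.as_dict()
    db_size = len(sequences)
    threshold = params.resolve_support(db_size)
    if threshold > db_size:
        warnings.warn(
            f"support threshold {threshold} exceeds database size {db_size}; "
            "no pattern can be frequent",
            stacklevel=2,
        )
        return PatternSetResult(patterns=[], params=params, db_size=db_size)

    max_wc = params.max_wc
    min_non_wc = params.min_non_wc
    sids = list(sequences)
    seq_list = [sequences[s] for s in sids]
    # occurrence lists carry integer sequence indices in the hot path
    reported: list[tuple[tuple[str, ...], list[int]]] = []

    longest = max(len(s) for s in seq_list)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * longest + 1000))

    def dfs(
        items: tuple[str, ...],
        occ: list[tuple[int, list[int]]],
        trailing_wc: int,
        non_wc: int,
        recheck_wc: bool,
    ) -> None:
        L = len(items)
        # wildcard uniformity: occurrences only ever die along a branch, so a
        # wildcard position may become uniform across the survivors; then it
        # specializes with unchanged support in every pattern of this
        # subtree, none of which can be closed.  Only worth rechecking when
        # the occurrence set shrank.
        if recheck_wc:
            for i, it in enumerate(items):
                if it != WILDCARD:
                    continue
                off = L - i
                first = None
                for si, ends in occ:
                    seq = seq_list[si]
                    for e in ends:
                        c = seq[e - off]
                        if first is None:
                            first = c
                        elif c != first:
                            break
                    else:
                        continue
                    first = None
                    break
                else:
                    if first is not None:
                        return
        # backward subsumption (BIDE-style BackScan): if one residue sits at
        # the same offset before *every* occurrence, each pattern of this
        # subtree left-extends with unchanged support, so none is closed
        for off in range(L + 1, L + max_wc + 2):
            first = None
            for si, ends in occ:
                seq = seq_list[si]
                for e in ends:
                    pos = e - off
                    if pos < 0:
                        break
                    c = seq[pos]
                    if first is None:
                        first = c
                    elif c != first:
                        break
                else:
                    continue
                first = None
                break
            else:
                if first is not None:
                    return

        # one-character look-ahead bucketed by next residue
        ext: dict[str, list[tuple[int, list[int]]]] = {}
        wc_occ: list[tuple[int, list[int]]] = []
        for si, ends in occ:
            seq = seq_list[si]
            n = len(seq)
            adv = [e + 1 for e in ends if e < n]
            if not adv:
                continue
            wc_occ.append((si, adv))
            buckets: dict[str, list[int]] = {}
            for e in adv:
                c = seq[e - 1]
                b = buckets.get(c)
                if b is None:
                    buckets[c] = [e]
                else:
                    b.append(e)
            for c, lst in buckets.items():
                el = ext.get(c)
                if el is None:
                    ext[c] = [(si, lst)]
                else:
                    el.append((si, lst))

        support = len(occ)
        if trailing_wc == 0 and non_wc >= min_non_wc:
            # closedness: the one-step look-ahead doubles as the k=0
            # right-extension check; remaining super-pattern classes are
            # scanned from the occurrence positions
            closed = all(len(lst) < support for lst in ext.values())
            if closed and max_wc > 0:
                for k in range(1, max_wc + 1):
                    inter: Optional[set[str]] = None
                    for si, ends in occ:
                        seq = seq_list[si]
                        n = len(seq)
                        chars = {seq[e + k] for e in ends if e + k < n}
                        inter = chars if inter is None else inter & chars
                        if not inter:
                            break
                    if inter:
                        closed = False
                        break
            if closed:
                for k in range(max_wc + 1):
                    inter = None
                    for si, ends in occ:
                        seq = seq_list[si]
                        chars = {
                            seq[e - L - k - 1]
                            for e in ends
                            if e - L - k - 1 >= 0
                        }
                        inter = chars if inter is None else inter & chars
                        if not inter:
                            break
                    if inter:
                        closed = False
                        break
            if closed:
                for i, item in enumerate(items):
                    if item != WILDCARD:
                        continue
                    inter = None
                    for si, ends in occ:
                        seq = seq_list[si]
                        chars = {seq[e - L + i] for e in ends}
                        inter = chars if inter is None else inter & chars
                        if not inter:
                            break
                    if inter:
                        closed = False
                        break
            if closed:
                reported.append((items, [si for si, _ in occ]))

        parent_total = sum(len(ends) for _, ends in occ)
        for c in sorted(ext):
            lst = ext[c]
            if len(lst) >= threshold:
                child_total = sum(len(ends) for _, ends in lst)
                dfs(items + (c,), lst, 0, non_wc + 1,
                    child_total < parent_total)
        if trailing_wc < max_wc and len(wc_occ) >= threshold:
            # wildcard subsumption: identical projection under some residue
            # means every pattern below the wildcard branch specializes with
            # unchanged support, so the branch holds no closed pattern
            if not any(lst == wc_occ for lst in ext.values()):
                child_total = sum(len(ends) for _, ends in wc_occ)
                dfs(items + (WILDCARD,), wc_occ, trailing_wc + 1, non_wc,
                    child_total < parent_total)

    initial: dict[str, list[tuple[int, list[int]]]] = {}
    for si, seq in enumerate(seq_list):
        buckets: dict[str, list[int]] = {}
        for pos, c in enumerate(seq):
            b = buckets.get(c)
            if b is None:
                buckets[c] = [pos + 1]
            else:
                b.append(pos + 1)
        for c, lst in buckets.items():
            el = initial.get(c)
            if el is None:
                initial[c] = [(si, lst)]
            else:
                el.append((si, lst))
    for c in sorted(initial):
        lst = initial[c]
        if len(lst) >= threshold:
            dfs((c,), lst, 0, 1, False)

    patterns = [
        Pattern(
            items=items,
            support_count=len(si_list),
            supporting_ids=frozenset(sids[si] for si in si_list),
        )
        for items, si_list in reported
    ]
    patterns.sort(key=lambda p: _sort_key(p.items))
    return PatternSetResult(patterns=patterns, params=params, db_size=db_size)


# ---------------------------------------------------------------------------
# brute-force oracle


def _is_super_pattern(sup: tuple[str, ...], sub: tuple[str, ...]) -> bool:
    """Containment: ``sub`` embeds in ``sup`` at some offset, each item of
    ``sub`` equal to the aligned item or itself a wildcard."""
    if len(sup) < len(sub):
        return False
    for off in range(len(sup) - len(sub) + 1):
        if all(
            s == WILDCARD or s == sup[off + i] for i, s in enumerate(sub)
        ):
            if sup != sub:
                return True
    return False


def _admissible(items: tuple[str, ...], max_wc: int) -> bool:
    if items[0] == WILDCARD or items[-1] == WILDCARD:
        return False
    run = 0
    for c in items:
        run = run + 1 if c == WILDCARD else 0
        if run > max_wc:
            return False
    return True


def enumerate_patterns_bruteforce(
    seqs: SequenceSet,
    params: Optional[MiningParams] = None,
    max_len: int = 10,
) -> PatternSetResult:
    """Independent closed-pattern enumeration for tiny inputs (test oracle).

    Candidate strings over alphabet ∪ {wildcard} are enumerated up to
    ``max_len`` (support-pruned: a prefix below threshold cannot recover),
    support is counted by regex scanning of every sequence, and closedness
    is decided by pairwise containment among the frequent candidates.
    Equals :func:`mine_closed_patterns` whenever every frequent pattern has
    length <= ``max_len``.
    """
    params = params or MiningParams()
    if len(seqs) == 0:
        raise ValueError("cannot mine an empty sequence set")
    sequences = seqs.as_dict()
    total = sum(len(s) for s in sequences.values())
    alphabet = sorted({c for s in sequences.values() for c in s})
    if total > 2000 or max_len > 12:
        raise ValueError(
            "brute-force enumeration is restricted to tiny inputs "
            f"(total residues {total} > 2000 or max_len {max_len} > 12)"
        )
    db_size = len(sequences)
    threshold = params.resolve_support(db_size)
    if threshold > db_size:
        warnings.warn(
            f"support threshold {threshold} exceeds database size {db_size}",
            stacklevel=2,
        )
        return PatternSetResult(patterns=[], params=params, db_size=db_size)

    def support_of(items: tuple[str, ...]) -> frozenset[str]:
        rx = re.compile(
            "".join("." if c == WILDCARD else re.escape(c) for c in items)
        )
        return frozenset(
            sid for sid, s in sequences.items() if rx.search(s)
        )

    # all frequent candidates with residue terminals and legal wildcard runs
    frequent: dict[tuple[str, ...], frozenset[str]] = {}
    symbols = alphabet + [WILDCARD]

    def extend(items: tuple[str, ...]) -> None:
        supp = support_of(items)
        if len(supp) < threshold:
            return
        if items[-1] != WILDCARD and _admissible(items, params.max_wc):
            frequent[items] = supp
        if len(items) == max_len:
            return
        for c in symbols:
            cand = items + (c,)
            run = 0
            for x in reversed(cand):
                if x != WILDCARD:
                    break
                run += 1
            if run > params.max_wc:
                continue
            extend(cand)

    for c in alphabet:
        extend((c,))

    closed: list[Pattern] = []
    for items, supp in frequent.items():
        if sum(1 for c in items if c != WILDCARD) < params.min_non_wc:
            continue
        dominated = any(
            other != items
            and len(osupp) == len(supp)
            and _is_super_pattern(other, items)
            for other, osupp in frequent.items()
        )
        if not dominated:
            closed.append(
                Pattern(
                    items=items,
                    support_count=len(supp),
                    supporting_ids=supp,
                )
            )
    closed.sort(key=lambda p: _sort_key(p.items))
    return PatternSetResult(patterns=closed, params=params, db_size=db_size)


# ---------------------------------------------------------------------------
# serialization


def write_patterns_tsv(
    result: PatternSetResult,
    path,
    weights: Optional[Iterable[float]] = None,
) -> None:
    """Write the pattern table as TSV.

    Columns: pattern (wildcard rendered as '.'), support_count, weight
    (empty unless provided), supporting_ids (comma-separated, sorted).
    """
    ws = list(weights) if weights is not None else None
    with open(path, "w") as fh:
        fh.write("pattern\tsupport_count\tweight\tsupporting_ids\n")
        for i, pat in enumerate(result.patterns):
            w = f"{ws[i]:.10g}" if ws is not None else ""
            ids = ",".join(sorted(pat.supporting_ids))
            fh.write(f"{pat.string}\t{pat.support_count}\t{w}\t{ids}\n")
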