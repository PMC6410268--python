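import random

import pytest
from hypothesis import given, settings, strategies as st

from pvtree.mining import (
    WILDCARD,
    MiningParams,
    Pattern,
    ProjectedDatabase,
    enumerate_patterns_bruteforce,
    grow,
    is_closed,
    mine_closed_patterns,
    write_patterns_tsv,
)
from pvtree.seq_io import Alphabet

from conftest import make_set, random_dna_set


class TestMiningParams:
    @pytest.mark.parametrize(
        "given_support,db_size,expected",
        [(0.03, 200, 6), (0.05, 200, 10), (0.03, 12, 2), (0.5, 3, 2), (4, 10, 4)],
    )
    def test_threshold_resolution(self, given_support, db_size, expected):
        assert MiningParams(given_support).resolve_support(db_size) == expected

    @pytest.mark.parametrize("bad", [0, -1, -0.5])
    def test_invalid_support_rejected(self, bad):
        with pytest.raises(ValueError):
            MiningParams(min_support=bad)


class TestWorkedExamples:
    def test_shared_prefix_only_pattern_survives(self, toy_proteins):
        # "CA" and "ACA" reach support 2 only; single residues fail min_non_wc
        r = mine_closed_patterns(toy_proteins, MiningParams(3, 2, 0))
        assert r.as_dict() == {"AC": 3}

    def test_subpattern_with_equal_support_is_not_closed(self):
        seqs = make_set({"s1": "AAA", "s2": "AAA"})
        r = mine_closed_patterns(seqs, MiningParams(2, 2, 0))
        assert r.as_dict() == {"AAA": 2}

    def test_wildcard_bridges_mismatch(self):
        seqs = make_set({"s1": "ACT", "s2": "AGT"})
        r = mine_closed_patterns(seqs, MiningParams(2, 2, 1))
        assert r.as_dict() == {"A.T": 2}

    def test_supporting_ids_recorded(self, toy_proteins):
        (pat,) = mine_closed_patterns(toy_proteins, MiningParams(3, 2, 0)).patterns
        assert pat.supporting_ids == {"s1", "s2", "s3"}

    def test_threshold_above_db_size_warns_and_returns_empty(self, toy_proteins):
        with pytest.warns(UserWarning):
            r = mine_closed_patterns(toy_proteins, MiningParams(7, 2, 0))
        assert len(r) == 0

    def test_empty_set_is_error(self):
        from pvtree.seq_io import SequenceSet

        with pytest.raises(ValueError):
            mine_closed_patterns(
                SequenceSet(records=[], alphabet=Alphabet.DNA), MiningParams(2)
            )


class TestGrow:
    def test_match_advance(self):
        pdb = ProjectedDatabase(sequences={"s1": "ACAC"}, ends={"s1": frozenset({1, 3})})
        pat, new = grow(Pattern.from_string("A"), pdb, "C")
        assert new.ends == {"s1": frozenset({2, 4})}
        assert pat.support_count == 1

    def test_no_match_empties_projection(self):
        pdb = ProjectedDatabase(sequences={"s1": "AG"}, ends={"s1": frozenset({1})})
        pat, new = grow(Pattern.from_string("A"), pdb, "C")
        assert new.ends == {} and pat.support_count == 0

    def test_wildcard_matches_any_residue(self):
        pdb = ProjectedDatabase(sequences={"s1": "AGT"}, ends={"s1": frozenset({1})})
        pat, new = grow(Pattern.from_string("A"), pdb, WILDCARD)
        assert new.ends == {"s1": frozenset({2})}
        assert pat.string == "A."


class TestIsClosed:
    def test_equal_support_superpattern_blocks(self):
        seqs = make_set({"s1": "AAA", "s2": "AAA"})
        assert not is_closed(Pattern.from_string("AA"), seqs, MiningParams(2, 2, 0))

    def test_closed_when_extensions_lose_support(self, toy_proteins):
        assert is_closed(
            Pattern.from_string("AC"), toy_proteins, MiningParams(3, 2, 0)
        )

    def test_whole_sequence_is_closed(self):
        seqs = make_set({"s1": "MKV", "s2": "AAAA"})
        assert is_closed(Pattern.from_string("MKV"), seqs, MiningParams(1, 2, 0))


class TestBruteForceOracle:
    def test_single_sequence_threshold_one(self):
        seqs = make_set({"s1": "ABC"})
        r = enumerate_patterns_bruteforce(seqs, MiningParams(1, 2, 0), max_len=5)
        assert r.as_dict() == {"ABC": 1}

    def test_size_guard(self):
        seqs = make_set({"s1": "MKV"})
        with pytest.raises(ValueError, match="tiny"):
            enumerate_patterns_bruteforce(seqs, MiningParams(1, 2, 0), max_len=20)

    def test_matches_miner_on_examples(self, toy_proteins):
        params = MiningParams(3, 2, 0)
        assert (
            enumerate_patterns_bruteforce(toy_proteins, params, 6).as_dict()
            == mine_closed_patterns(toy_proteins, params).as_dict()
        )


class TestMinerOracleEquivalence:
    """Randomized cross-validation of the projected-database miner."""

    def test_random_instances_match_bruteforce(self):
        rng = random.Random(42)
        for _ in range(120):
            seqs = random_dna_set(rng)
            params = MiningParams(
                rng.randint(2, len(seqs)), rng.randint(1, 3), rng.randint(0, 3)
            )
            mined = mine_closed_patterns(seqs, params)
            brute = enumerate_patterns_bruteforce(seqs, params, max_len=10)
            assert mined.as_dict() == brute.as_dict()
            assert [p.supporting_ids for p in mined.patterns] == [
                p.supporting_ids for p in brute.patterns
            ]

    @given(st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_property_miner_equals_oracle(self, case_seed):
        rng = random.Random(case_seed)
        seqs = random_dna_set(rng)
        params = MiningParams(2, rng.randint(1, 2), rng.randint(0, 2))
        mined = mine_closed_patterns(seqs, params)
        brute = enumerate_patterns_bruteforce(seqs, params, max_len=10)
        assert mined.as_dict() == brute.as_dict()


class TestMinerInvariants:
    @staticmethod
    def _count_support(pattern, seqs):
        rx = pattern.regex()
        return sum(1 for rec in seqs if rx.search(rec.residues))

    def test_support_recheck_and_antimonotonicity(self):
        rng = random.Random(7)
        for _ in range(25):
            seqs = random_dna_set(rng)
            params = MiningParams(2, 2, 2)
            result = mine_closed_patterns(seqs, params)
            for pat in result.patterns:
                assert self._count_support(pat, seqs) == pat.support_count
                # every prefix ending in a residue is at least as frequent
                for cut in range(1, pat.length):
                    prefix = Pattern(items=pat.items[:cut])
                    if prefix.items[-1] == WILDCARD:
                        continue
                    assert (
                        self._count_support(prefix, seqs) >= pat.support_count
                    )

    def test_determinism(self):
        rng = random.Random(13)
        seqs = random_dna_set(rng)
        params = MiningParams(2, 2, 2)
        a = mine_closed_patterns(seqs, params)
        b = mine_closed_patterns(seqs, params)
        assert [(p.string, p.support_count) for p in a.patterns] == [
            (p.string, p.support_count) for p in b.patterns
        ]

    def test_raising_support_only_filters(self):
        # closedness does not depend on the threshold, so raising it must
        # select exactly the subset of already-mined patterns that clear it
        rng = random.Random(99)
        for _ in range(15):
            seqs = random_dna_set(rng, n_min=4)
            lower = mine_closed_patterns(seqs, MiningParams(2, 2, 1))
            higher = mine_closed_patterns(seqs, MiningParams(3, 2, 1))
            assert higher.as_dict() == {
                p.string: p.support_count
                for p in lower.patterns
                if p.support_count >= 3
            }

    def test_constraints_hold_on_reported_patterns(self):
        rng = random.Random(5)
        seqs = random_dna_set(rng, n_min=4, n_max=6, l_min=8, l_max=10)
        params = MiningParams(2, 2, 1)
        for pat in mine_closed_patterns(seqs, params).patterns:
            assert pat.items[0] != WILDCARD and pat.items[-1] != WILDCARD
            assert pat.non_wc >= 2
            run = 0
            for c in pat.items:
                run = run + 1 if c == WILDCARD else 0
                assert run <= 1


def test_patterns_tsv_serialization(tmp_path, toy_proteins):
    result = mine_closed_patterns(toy_proteins, MiningParams(3, 2, 0))
    out = tmp_path / "patterns.tsv"
    write_patterns_tsv(result, out, weights=[0.0])
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == [
        "pattern", "support_count", "weight", "supporting_ids",
    ]
    assert lines[1].split("\t") == ["AC", "3", "0", "s1,s2,s3"]
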