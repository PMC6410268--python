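import random

import pytest

from pvtree.seq_io import Alphabet, SequenceRecord, SequenceSet


def make_set(mapping, alphabet=Alphabet.PROTEIN):
    """SequenceSet from an {id: residues} mapping, preserving order."""
    return SequenceSet(
        records=[SequenceRecord(id=k, residues=v) for k, v in mapping.items()],
        alphabet=alphabet,
    )


def random_dna_set(rng: random.Random, n_min=3, n_max=6, l_min=4, l_max=10):
    """Small random nucleotide set for miner-vs-oracle comparisons."""
    n = rng.randint(n_min, n_max)
    return make_set(
        {
            f"s{i}": "".join(
                rng.choice("ACGT") for _ in range(rng.randint(l_min, l_max))
            )
            for i in range(n)
        },
        alphabet=Alphabet.DNA,
    )


@pytest.fixture
def toy_proteins():
    return make_set({"s1": "ACAC", "s2": "ACGT", "s3": "ACAA"})
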