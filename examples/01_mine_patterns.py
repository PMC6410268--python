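"""Mine closed sequential patterns with wildcards from a toy family.

Three short peptides share a conserved N-terminal motif; one position
varies, so the miner bridges it with a wildcard (rendered '.').
"""

from pvtree import MiningParams, SequenceRecord, SequenceSet, mine_closed_patterns

seqs = SequenceSet(
    records=[
        SequenceRecord(id="pepA", residues="MKVACTWLE"),
        SequenceRecord(id="pepB", residues="MKVAGTWLD"),
        SequenceRecord(id="pepC", residues="MKVACTWLE"),
    ],
)

result = mine_closed_patterns(seqs, MiningParams(min_support=3, min_non_wc=2, max_wc=1))
print(f"{len(result)} closed patterns supported by all {seqs.db_size} sequences")
for pat in result:
    print(f"  {pat.string:<12} support={pat.support_count} length={pat.length}")
# Each printed pattern occurs in every sequence and has no equally frequent
# super-pattern: e.g. the wildcard in 'MKVA.TWL' bridges the C/G mismatch.
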