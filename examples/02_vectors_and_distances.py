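"""From mined patterns to weighted vectors and Jensen-Shannon distances.

Patterns are weighted by W = PatLength * log2(DBSize / PatSup): longer and
rarer patterns count more, and a pattern found in every sequence weighs 0.
"""

from pvtree import (
    MiningParams,
    SequenceRecord,
    SequenceSet,
    build_feature_space,
    distance_matrix,
    mine_closed_patterns,
    vectorize_sequences,
)

seqs = SequenceSet(
    records=[
        SequenceRecord(id="a1", residues="MKVLWDERTACGH"),
        SequenceRecord(id="a2", residues="MKVLWDERSACGH"),
        SequenceRecord(id="b1", residues="PFYNQSTHWKVLR"),
        SequenceRecord(id="b2", residues="PFYNQATHWKVLR"),
    ],
)

mined = mine_closed_patterns(seqs, MiningParams(min_support=2, min_non_wc=2, max_wc=1))
space = build_feature_space(mined)
print(f"feature space: {len(space)} patterns, weights 0..{space.weights.max():.2f}")

vectors = vectorize_sequences(seqs, space, mode="weighted")
m = distance_matrix(vectors)
print("pairwise JS distances (0 = identical pattern profile, 1 = disjoint):")
for i, lab in enumerate(m.labels):
    row = "  ".join(f"{v:.3f}" for v in m.d[i])
    print(f"  {lab}  {row}")
# The a-pair and b-pair are near 0 within pairs and near 1 across pairs:
# the two families share almost no mined pattern.
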