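# pvtree

Alignment-free phylogeny reconstruction from closed sequential patterns.

`pvtree` rebuilds phylogenetic trees from **unaligned** protein or
nucleotide sequences. Instead of a multiple sequence alignment — which
becomes unreliable below ~20% identity — it mines the sequences for
*closed frequent sequential patterns*: contiguous motifs over the residue
alphabet, optionally interleaved with single-residue wildcards, that occur
in at least a minimum number of sequences and have no equally frequent
super-pattern. The mined patterns form a feature space in which every
sequence becomes a weighted presence vector, pairwise distances are
measured with the Jensen–Shannon divergence, and an unrooted tree is built
with Neighbor Joining. The package targets large, divergent sequence
families where alignment-based pipelines break down.

## Method

1. **Mining.** Depth-first pattern growth over projected databases finds
   every pattern *P* with support ≥ *min_support* (counted as distinct
   sequences), at least *min_non_wc* residue positions, no run of more than
   *max_wc* consecutive wildcards, and residues at both ends. Only *closed*
   patterns are kept: no admissible super-pattern (left/right extension or
   wildcard specialization) has identical support.
2. **Weighting.** Each pattern receives the IDF-like weight

   $$W = \mathrm{PatLength} \times \log_2\frac{\mathrm{DBSize}}{\mathrm{PatSup}}$$

   so longer and rarer patterns dominate and ubiquitous ones vanish.
3. **Vectors and distances.** Sequence *i* becomes the vector with entry
   $W_j$ where pattern *j* occurs in it and 0 elsewhere (a binary variant
   exists for highly similar families). Vectors are normalized to
   distributions $P, Q$ and compared with
   $JS(P,Q) = \tfrac12 KL(P,M) + \tfrac12 KL(Q,M)$, $M = (P+Q)/2$, in log
   base 2, giving distances in [0, 1].
4. **Tree.** Saitou–Nei Neighbor Joining on the distance matrix; trees are
   serialized as Newick. Robinson–Foulds symmetric difference scores a
   reconstruction against a reference topology.

A tree-guided sequence-evolution simulator (random Yule guide tree,
per-site substitutions, geometric-length insertions/deletions) makes the
whole pipeline testable end to end without external data.

## Worked example

```python
from pvtree import (EvolutionParams, PipelineConfig, mean_pairwise_identity,
                    rf_distance, run_pipeline, simulate_family)

sim = simulate_family(12, EvolutionParams(root_length=300, seed=5))
print(f"mean pairwise identity {100 * mean_pairwise_identity(sim.leaves):.1f}%")
result = run_pipeline(PipelineConfig(), seqs=sim.leaves)
print(f"mined {len(result.patterns)} closed patterns")
print(f"RF distance to the true tree: {rf_distance(sim.guide_tree, result.tree)}")
```

prints (exactly, runs are deterministic):

```
mean pairwise identity 61.5%
mined 3574 closed patterns
RF distance to the true tree: 0
```

A 12-taxon family at ~62% identity yields ~3.6k closed patterns under the
default parameters (support 0.03, ≥2 residues per pattern, wildcard runs
≤ 2, weighted vectors); RF = 0 means every non-trivial split of the true
history was recovered. The `examples/` directory holds one short script
per capability (mining, vectors/distances, simulation + recovery,
parameter sweeps).

## Command line

```bash
pvtree simulate --leaves 12 --length 300 --seed 1 \
    --out-fasta leaves.fa --out-tree true.nwk
pvtree build leaves.fa --out-tree inferred.nwk --out-matrix dist.phy \
    --out-patterns patterns.tsv
pvtree compare true.nwk inferred.nwk        # prints the RF distance
pvtree sweep leaves.fa true.nwk --support 2 --support 4 --max-wc 0 --max-wc 2
```

`build` accepts a YAML config file (`--config`); command-line flags win
over file values, which win over the defaults.

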