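"""End-to-end reconstruction: mine -> weight -> vectorize -> distance -> NJ.

Defaults follow the divergent-sequence setting: support fraction 0.03,
at least 2 non-wildcard residues per pattern, wildcard runs of at most 2,
weighted vectors, plain JS distances.  The pipeline is fully
deterministic, so identical inputs and configuration reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import distance as _distance
from . import mining as _mining
from . import seq_io as _seq_io
from . import tree as _tree
from . import vectorize as _vectorize

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("pvtree")


@dataclass
class PipelineConfig:
    """Resolved parameters of one reconstruction run."""

    input_fasta: Optional[Union[str, Path]] = None
    alphabet: str = "auto"
    min_support: Union[int, float] = 0.03
    min_non_wc: int = 2
    max_wc: int = 2
    vector_mode: str = "weighted"
    distance_variant: str = "js"  # "js" or "sqrt-js"
    out_tree: Optional[Union[str, Path]] = None
    out_matrix: Optional[Union[str, Path]] = None
    out_matrix_tsv: Optional[Union[str, Path]] = None
    out_patterns: Optional[Union[str, Path]] = None
    out_manifest: Optional[Union[str, Path]] = None

    def mining_params(self) -> _mining.MiningParams:
        return _mining.MiningParams(
            min_support=self.min_support,
            min_non_wc=self.min_non_wc,
            max_wc=self.max_wc,
        )


@dataclass
class PipelineResult:
    tree: _tree.PhyloTree
    matrix: _distance.DistanceMatrix
    patterns: _mining.PatternSetResult
    feature_space: _vectorize.FeatureSpace
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    cfg: PipelineConfig,
    seqs: Optional[_seq_io.SequenceSet] = None,
) -> PipelineResult:
    """Run the full reconstruction on ``seqs`` (or ``cfg.input_fasta``).

    Intermediate artifacts are written wherever the config names a path;
    a manifest with resolved parameters, pattern count and per-stage
    runtimes is always assembled (and logged).
    """
    if seqs is None:
        if cfg.input_fasta is None:
            raise ValueError("no input: provide a SequenceSet or input_fasta")
        seqs = _seq_io.read_fasta(cfg.input_fasta, alphabet=cfg.alphabet)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to build a tree")
    if cfg.distance_variant not in ("js", "sqrt-js"):
        raise ValueError(f"unknown distance variant: {cfg.distance_variant!r}")

    params = cfg.mining_params()
    threshold = params.resolve_support(seqs.db_size)
    logger.info(
        "mining %d sequences (absolute support threshold %d, "
        "min_non_wc=%d, max_wc=%d)",
        seqs.db_size, threshold, params.min_non_wc, params.max_wc,
    )
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    patterns = _mining.mine_closed_patterns(seqs, params)
    timings["mine"] = time.perf_counter() - t0
    logger.info("mined %d closed patterns in %.2fs",
                len(patterns), timings["mine"])
    if len(patterns) == 0:
        raise ValueError(
            "no pattern satisfies the thresholds; lower min_support or "
            "min_non_wc (divergent sets need small support values)"
        )

    t0 = time.perf_counter()
    space = _vectorize.build_feature_space(patterns)
    vectors = _vectorize.vectorize_sequences(seqs, space, mode=cfg.vector_mode)
    timings["vectorize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matrix = _distance.distance_matrix(
        vectors, sqrt=(cfg.distance_variant == "sqrt-js")
    )
    timings["distance"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    nj_tree = _tree.neighbor_joining(matrix)
    timings["tree"] = time.perf_counter() - t0

    manifest = {
        "db_size": seqs.db_size,
        "alphabet": seqs.alphabet.value,
        "min_support": cfg.min_support,
        "absolute_support_threshold": threshold,
        "min_non_wc": params.min_non_wc,
        "max_wc": params.max_wc,
        "vector_mode": cfg.vector_mode,
        "distance_variant": cfg.distance_variant,
        "n_patterns": len(patterns),
        "stage_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    logger.info("run manifest: %s", json.dumps(manifest))

    if cfg.out_patterns:
        _mining.write_patterns_tsv(patterns, cfg.out_patterns,
                                   weights=space.weights)
    if cfg.out_matrix:
        _distance.write_phylip(matrix, cfg.out_matrix)
    if cfg.out_matrix_tsv:
        _distance.write_tsv(matrix, cfg.out_matrix_tsv)
    if cfg.out_tree:
        _tree.write_newick(nj_tree, cfg.out_tree)
    if cfg.out_manifest:
        with open(cfg.out_manifest, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        tree=nj_tree,
        matrix=matrix,
        patterns=patterns,
        feature_space=space,
        manifest=manifest,
    )
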