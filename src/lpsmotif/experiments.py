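"""Reproducible study-scale experiments on the default synthetic bundle.

These functions run the package's main computations end-to-end at the
default study conditions (1000 genes, 10% pro-inflammatory / 2%
antibacterial classes, one planted PWM at insertion probability 0.6 with 8
information-content-matched decoys, duplicate arrays at 5% CV) and score
the results against the generator's truth manifest.  They back both the
acceptance script and the heavier acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import classify_matrix, random_gene_pattern_null
from .pipeline import PipelineParams, run_pipeline
from .simulate import SyntheticConfig, generate_bundle, generate_expression
from .validation import validate


@dataclass
class RecoveryScores:
    pro_sensitivity: float
    pro_precision: float
    anti_sensitivity: float
    anti_precision: float


def classification_recovery(seeds, config: SyntheticConfig | None = None) -> RecoveryScores:
    """Mean planted-class recovery of the phenotype filter over seeds."""
    ps, pp, as_, ap = [], [], [], []
    for seed in seeds:
        cfg = config or SyntheticConfig()
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": int(seed)})
        matrix, manifest = generate_expression(cfg)
        result = classify_matrix(matrix)
        truth_pro = set(manifest.genes_of_class("pro"))
        truth_anti = set(manifest.genes_of_class("anti"))
        got_pro, got_anti = set(result.pro_genes), set(result.anti_genes)
        ps.append(len(got_pro & truth_pro) / max(len(truth_pro), 1))
        pp.append(len(got_pro & truth_pro) / max(len(got_pro), 1))
        as_.append(len(got_anti & truth_anti) / max(len(truth_anti), 1))
        ap.append(len(got_anti & truth_anti) / max(len(got_anti), 1))
    return RecoveryScores(float(np.mean(ps)), float(np.mean(pp)),
                          float(np.mean(as_)), float(np.mean(ap)))


@dataclass
class ConsensusSweep:
    seeds: list[int]
    consensus_hits: int
    tcs_top_hits: int
    affinity_top_hits: int
    per_seed: list[dict] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.seeds)


def consensus_recovery_sweep(
    seeds,
    config: SyntheticConfig | None = None,
    params: PipelineParams | None = None,
) -> ConsensusSweep:
    """Full pipeline per seed; scores planted-accession recovery.

    For each seed the default bundle is regenerated and classified, the
    three engines run on the classified pro-inflammatory set, and the
    consensus computed.  Scored facts per seed: whether the planted
    accession survives the three-way intersection, and whether the TCS and
    affinity engines rank it first.
    """
    seeds = [int(s) for s in seeds]
    sweep = ConsensusSweep(seeds, 0, 0, 0)
    for seed in seeds:
        cfg = config or SyntheticConfig()
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": seed})
        bundle = generate_bundle(cfg)
        run_params = params or PipelineParams()
        run_params = PipelineParams(**{**run_params.__dict__, "seed": seed})
        result = run_pipeline(bundle.matrix, bundle.promoters, bundle.library,
                              bundle.targets, params=run_params)
        planted = bundle.planted_accessions[0]
        in_consensus = planted in result.consensus_accessions
        tcs_first = result.predictions["tcs"][0].accession == planted
        aff_first = result.predictions["affinity"][0].accession == planted
        sweep.consensus_hits += in_consensus
        sweep.tcs_top_hits += tcs_first
        sweep.affinity_top_hits += aff_first
        sweep.per_seed.append({
            "seed": seed,
            "planted_in_consensus": in_consensus,
            "tcs_top": tcs_first,
            "affinity_top": aff_first,
            "consensus": result.consensus_accessions,
            "n_pro_genes": len(result.gene_set),
        })
    return sweep


def validation_summary(seed: int, config: SyntheticConfig | None = None) -> dict:
    """Signature size, planted-target overlap and random-set null counts."""
    cfg = config or SyntheticConfig()
    cfg = SyntheticConfig(**{**cfg.__dict__, "seed": int(seed)})
    bundle = generate_bundle(cfg)
    report = validate(bundle.matrix, bundle.targets, seed=int(seed))
    planted_targets = set(bundle.manifest.planted_targets.get("PLT001", []))
    null_counts = random_gene_pattern_null(
        bundle.matrix, set_size=max(report.overlap_count, 1), n_sets=10, seed=int(seed))
    return {
        "signature_size": report.signature_size,
        "overlap_count": report.overlap_count,
        "pattern_pass_count": report.pattern_pass_count,
        "planted_targets_recovered": len(planted_targets & set(report.overlap_genes)),
        "n_planted_targets": len(planted_targets),
        "random_null_mean": float(np.mean(null_counts)),
        "random_null_max": int(max(null_counts)),
        "n_genes": cfg.n_genes,
    }
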