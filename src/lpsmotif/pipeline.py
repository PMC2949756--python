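"""End-to-end orchestration: classify -> three engines -> consensus -> validate.

A run takes an expression matrix, a promoter FASTA covering the whole gene
universe, a PWM library and a curated target list (together a "bundle",
whether synthetic or loaded from files), classifies the phenotype gene set,
runs the three motif engines on it, intersects their top-70% retained
predictions into a consensus, and validates curated targets against the
two-fold signature.  A companion random-gene run with a random response
supplies the test-vs-random contrast.

Engine problem sizes default to values sized for a ~1000-gene bundle with
~100-gene phenotype sets; every knob is in :class:`PipelineParams` and is
recorded in the run manifest, so a run is fully reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import (
    PWM,
    ExpressionMatrix,
    PromoterSequence,
    TargetAssociation,
    normalize_symbol,
    read_expression_matrix,
    read_fasta_promoters,
    read_pwm_library,
    read_target_lists,
    write_pwm_tsv,
)
from .classify import PRO, ANTI, ClassificationResult, classify_matrix
from .consensus import (
    ConsensusMotif,
    ContrastRow,
    MotifPrediction,
    contrast_test_vs_random,
    intersect_engines,
    map_discovery_predictions,
    top_fraction,
)
from .discovery import discover_motifs
from .pastaa import associate_library
from .tcs import build_count_matrix, random_response, run_tcs
from .validation import ValidationReport, validate

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc


@dataclass
class PipelineParams:
    """All tunables of one pipeline run."""

    alpha: float = 0.05
    fold: float = 2.0
    fraction: float = 0.70
    gene_set: str = PRO           # which phenotype class the engines analyse
    test_contrast: str = "N_vs_TL"
    # discovery engine (sized for ~100 promoters of ~1.3 kb)
    n_motifs: int = 3
    widths: tuple[int, ...] = (8, 12)
    max_width: int = 15
    n_starts: int = 30
    em_max_iter: int = 60
    em_tol: float = 1e-3
    n_shuffles: int = 5
    match_threshold: float = 0.75
    match_min_overlap: int = 4
    # TCS engine
    tcs_subset_size: int = 20
    tcs_iterations: int = 200
    tcs_normalization: str = "mean"
    # affinity engine
    cutoff_grid: tuple[int, ...] = (5, 10, 20, 50, 100, 200)
    #: map de-novo motifs to accessions before top-70% retention (default)
    #: or retain first and map the survivors
    map_before_retention: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    classification: ClassificationResult
    gene_set: list[str]
    predictions: dict[str, list[MotifPrediction]]      # raw, accession-mapped
    retained: dict[str, list[MotifPrediction]]         # after top-70%
    consensus: list[ConsensusMotif]
    validation: ValidationReport
    manifest: dict
    contrast: list[ContrastRow] | None = None

    @property
    def consensus_accessions(self) -> list[str]:
        return [c.accession for c in self.consensus]


def load_bundle_files(
    matrix_path, promoters_path, library_path, targets_path
) -> tuple[ExpressionMatrix, list[PromoterSequence], list[PWM], list[TargetAssociation]]:
    for name, p in (("matrix", matrix_path), ("promoters", promoters_path),
                    ("library", library_path), ("targets", targets_path)):
        if p is None:
            raise ValueError(f"pipeline input {name!r} is not configured")
        if not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name!r} not found: {p}")
    return (
        read_expression_matrix(matrix_path),
        read_fasta_promoters(promoters_path),
        read_pwm_library(library_path),
        read_target_lists(targets_path),
    )


def _promoter_subset(promoters: list[PromoterSequence], genes: list[str]) -> list[PromoterSequence]:
    keys = {normalize_symbol(g) for g in genes}
    subset = [p for p in promoters if normalize_symbol(p.gene_id) in keys]
    if not subset:
        raise ValueError("no promoters available for the selected gene set")
    return subset


def _engine_predictions(
    promoters_all: list[PromoterSequence],
    promoters_set: list[PromoterSequence],
    library: list[PWM],
    response: dict[str, float],
    specificity: dict[str, float],
    params: PipelineParams,
    seed: int,
) -> tuple[dict[str, list[MotifPrediction]], list[MotifPrediction] | None]:
    """Run the three engines and express every output as accession-scored
    predictions.

    Returns the per-engine predictions and, when retention precedes
    accession mapping (``map_before_retention=False``), the already
    retained discovery list (mapping order changes what survives).
    """
    # 1. EM discovery on the gene-set promoters, mapped onto the library
    motifs = discover_motifs(
        promoters_set,
        n_motifs=params.n_motifs,
        max_width=params.max_width,
        widths=params.widths,
        seed=seed,
        n_starts=params.n_starts,
        max_iter=params.em_max_iter,
        tol=params.em_tol,
        n_shuffles=params.n_shuffles,
    )
    discovery_retained: list[MotifPrediction] | None = None
    if not params.map_before_retention:
        denovo = [MotifPrediction("discovery", m.motif_id, m.e_value) for m in motifs]
        kept = {p.accession for p in top_fraction(denovo, params.fraction)}
        discovery_retained = map_discovery_predictions(
            [m for m in motifs if m.motif_id in kept], library,
            min_overlap=params.match_min_overlap, threshold=params.match_threshold,
        )
    discovery_preds = map_discovery_predictions(
        motifs, library,
        min_overlap=params.match_min_overlap, threshold=params.match_threshold,
    )

    # 2. TCS on the gene-set promoters with the expression response
    y = np.array([response[p.gene_id] for p in promoters_set])
    subset = min(params.tcs_subset_size, len(library))
    tcs_results = run_tcs(
        promoters_set, y, motif_universe=library,
        subset_size=subset, n_iterations=params.tcs_iterations,
        seed=seed, normalization=params.tcs_normalization,
    )
    tf_by_acc = {p.accession: p.tf_name for p in library}
    tcs_preds = [
        MotifPrediction("tcs", r.motif_id, r.tcs, tf_name=tf_by_acc.get(r.motif_id, ""))
        for r in tcs_results
    ]

    # 3. affinity association over the full promoter universe
    assoc = associate_library(library, promoters_all, specificity,
                              cutoff_grid=params.cutoff_grid)
    affinity_preds = [
        MotifPrediction("affinity", r.matrix_accession, r.best_p, tf_name=r.tf_name)
        for r in assoc
    ]
    predictions = {"discovery": discovery_preds, "tcs": tcs_preds, "affinity": affinity_preds}
    return predictions, discovery_retained


def _log2_ratio(matrix: ExpressionMatrix, num: str, den: str) -> dict[str, float]:
    collapsed = matrix.collapse_by_symbol()
    out: dict[str, float] = {}
    for rec in collapsed:
        a, b = rec.mean(num), rec.mean(den)
        out[rec.gene_symbol] = float(np.log2(a / b)) if a > 0 and b > 0 else 0.0
    return out


def run_pipeline(
    matrix: ExpressionMatrix,
    promoters: list[PromoterSequence],
    library: list[PWM],
    targets: list[TargetAssociation],
    params: PipelineParams | None = None,
    second_matrix: ExpressionMatrix | None = None,
    out_dir=None,
) -> PipelineResult:
    """Execute the full workflow on one bundle.

    Stage order: phenotype classification; promoter selection for the
    phenotype gene set; the three engines; accession mapping and top-70%
    retention; three-way intersection; literature-target validation.
    Outputs are written as TSV/JSON under ``out_dir`` when given.
    """
    params = params or PipelineParams()
    if not library:
        raise ValueError("pipeline requires a non-empty PWM library for consensus")

    with _stage("classification"):
        classification = classify_matrix(matrix, alpha=params.alpha,
                                         contrast=params.test_contrast)
        gene_set = classification.pro_genes if params.gene_set == PRO else classification.anti_genes
        if not gene_set:
            raise ValueError(f"classification produced an empty {params.gene_set} gene set")
        promoters_set = _promoter_subset(promoters, gene_set)

    # tolerance contrast as TCS response; induction contrast as specificity
    response = _log2_ratio(matrix, "TL", "NL")
    specificity = _log2_ratio(matrix, "NL", "N")
    for p in promoters:
        response.setdefault(p.gene_id, 0.0)
        specificity.setdefault(p.gene_id, 0.0)

    with _stage("motif_engines"):
        predictions, discovery_retained = _engine_predictions(
            promoters, promoters_set, library, response, specificity, params, params.seed
        )
    with _stage("consensus"):
        retained = {e: top_fraction(preds, params.fraction)
                    for e, preds in predictions.items()}
        if discovery_retained is not None:
            retained["discovery"] = discovery_retained
        consensus = intersect_engines(retained)
    with _stage("validation"):
        report = validate(matrix, targets, second_matrix=second_matrix,
                          seed=params.seed, fold=params.fold)

    manifest = {
        "config": asdict(params),
        "config_hash": params.config_hash(),
        "seed": params.seed,
        "gene_set": params.gene_set,
        "n_genes": len(gene_set),
        "counts": {
            **classification.counts,
            "signature_genes": report.signature_size,
            "retained": {e: len(v) for e, v in retained.items()},
            "consensus": len(consensus),
        },
    }
    result = PipelineResult(classification, gene_set, predictions, retained,
                            consensus, report, manifest)
    if out_dir is not None:
        _write_run(result, Path(out_dir))
    logger.info("pipeline counts: %s", manifest["counts"])
    return result


def run_random_background(
    matrix: ExpressionMatrix,
    promoters: list[PromoterSequence],
    library: list[PWM],
    n_random_genes: int,
    params: PipelineParams | None = None,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Companion run on a random unclassified gene set with a random response.

    Samples ``n_random_genes`` genes without replacement from the pool of
    unclassified genes that have promoters, draws their TCS response
    uniformly within the observed response range, gives the affinity engine
    a random specificity ranking, and runs the three engines plus top-70%
    retention.  Returns the retained predictions and the run manifest.
    """
    params = params or PipelineParams()
    if n_random_genes < 1:
        raise ValueError("n_random_genes must be >= 1")
    classification = classify_matrix(matrix, alpha=params.alpha, contrast=params.test_contrast)
    classified = {normalize_symbol(g) for g in classification.pro_genes}
    classified |= {normalize_symbol(g) for g in classification.anti_genes}
    pool = [p.gene_id for p in promoters if normalize_symbol(p.gene_id) not in classified]
    if n_random_genes > len(pool):
        raise ValueError(f"random pool has only {len(pool)} genes")
    rng = np.random.default_rng(seed)
    random_genes = sorted(rng.choice(pool, size=n_random_genes, replace=False))
    promoters_set = _promoter_subset(promoters, random_genes)

    true_response = _log2_ratio(matrix, "TL", "NL")
    lo = min(true_response.values())
    hi = max(true_response.values())
    rand_vals = random_response(lo, hi, len(promoters_set), seed=seed)
    response = {p.gene_id: float(v) for p, v in zip(promoters_set, rand_vals)}
    spec_vals = random_response(lo, hi, len(promoters), seed=seed + 1)
    specificity = {p.gene_id: float(v) for p, v in zip(promoters, spec_vals)}

    predictions, discovery_retained = _engine_predictions(
        promoters, promoters_set, library, response, specificity, params, seed
    )
    retained = {e: top_fraction(preds, params.fraction) for e, preds in predictions.items()}
    if discovery_retained is not None:
        retained["discovery"] = discovery_retained
    manifest = {
        "config": asdict(params),
        "config_hash": params.config_hash(),
        "seed": seed,
        "gene_set": "random_background",
        "n_genes": n_random_genes,
        "genes": list(map(str, random_genes)),
    }
    out = {"predictions": predictions, "retained": retained, "manifest": manifest}
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for engine, preds in retained.items():
            _write_predictions(preds, out_path / f"random_{engine}.tsv")
        (out_path / "random_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def contrast_with_random(result: PipelineResult, random_run: dict) -> list[ContrastRow]:
    rows = contrast_test_vs_random(
        result.consensus, random_run["retained"],
        test_manifest=result.manifest["config"],
        random_manifest=random_run["manifest"]["config"],
    )
    result.contrast = rows
    return rows


def _write_predictions(preds: list[MotifPrediction], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("engine\taccession\ttf_name\tscore\n")
        for p in preds:
            fh.write(f"{p.engine}\t{p.accession}\t{p.tf_name}\t{p.score:.6g}\n")


def _write_run(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "phenotype_calls.tsv").open("w") as fh:
        fh.write("probe_id\tgene_symbol\tn_avg\tnl_avg\ttl_avg\tr1\tr2\tp_value\tlabel\n")
        for c in result.classification.calls:
            r1 = "" if c.r1 is None else f"{c.r1:.6g}"
            r2 = "" if c.r2 is None else f"{c.r2:.6g}"
            p = "" if c.p_value is None else f"{c.p_value:.6g}"
            fh.write(f"{c.probe_id}\t{c.gene_symbol}\t{c.n_avg:.6g}\t{c.nl_avg:.6g}"
                     f"\t{c.tl_avg:.6g}\t{r1}\t{r2}\t{p}\t{c.label}\n")
    for engine, preds in result.predictions.items():
        _write_predictions(preds, out_dir / f"engine_{engine}.tsv")
    for engine, preds in result.retained.items():
        _write_predictions(preds, out_dir / f"retained_{engine}.tsv")
    with (out_dir / "consensus.tsv").open("w") as fh:
        fh.write("accession\ttf_name\tdiscovery_score\ttcs_score\taffinity_score\n")
        for c in result.consensus:
            fh.write(f"{c.accession}\t{c.tf_name}\t{c.scores['discovery']:.6g}"
                     f"\t{c.scores['tcs']:.6g}\t{c.scores['affinity']:.6g}\n")
    result.validation.to_json(out_dir / "validation.json")
    (out_dir / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )
    if result.contrast is not None:
        with (out_dir / "contrast.tsv").open("w") as fh:
            fh.write("accession\tengine\ttest_score\trandom_score\tbetter\n")
            for row in result.contrast:
                rs = "-" if row.random_score is None else f"{row.random_score:.6g}"
                fh.write(f"{row.accession}\t{row.engine}\t{row.test_score:.6g}\t{rs}\t{row.better}\n")
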