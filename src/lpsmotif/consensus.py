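"""Cross-engine consensus: top-70% selection, library mapping, intersection.

Each engine emits scored predictions with its own score orientation
(discovery: E-value, lower better; TCS: higher better; affinity: p-value,
lower better).  Per engine the best 70% are retained (ceil rounding,
boundary ties all kept), de-novo motifs are mapped to library accessions by
an ungapped column-correlation comparator, and the accessions present in
all three retained sets form the consensus.  A companion random-gene run
supplies the test-vs-random score contrast table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import PWM

logger = logging.getLogger(__name__)

ENGINES = ("discovery", "tcs", "affinity")
ENGINE_ORIENTATION = {
    "discovery": "lower_better",
    "tcs": "higher_better",
    "affinity": "lower_better",
}


@dataclass
class MotifPrediction:
    engine: str
    accession: str
    score: float
    tf_name: str = ""
    source_id: str = ""  # de-novo motif id before library mapping

    def __post_init__(self) -> None:
        if self.engine not in ENGINE_ORIENTATION:
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def orientation(self) -> str:
        return ENGINE_ORIENTATION[self.engine]


@dataclass
class ConsensusMotif:
    accession: str
    tf_name: str
    scores: dict[str, float]  # engine -> retained score


@dataclass
class PwmMatch:
    accession: str
    tf_name: str
    similarity: float
    offset: int
    orientation: str  # + or -


def top_fraction(predictions: list[MotifPrediction], fraction: float = 0.70) -> list[MotifPrediction]:
    """Retain the best ``ceil(fraction * n)`` predictions per engine orientation.

    Ties at the boundary score are all retained.  The input must be
    homogeneous in engine.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not predictions:
        return []
    engines = {p.engine for p in predictions}
    if len(engines) > 1:
        raise ValueError(f"mixed engines in one prediction list: {sorted(engines)}")
    lower = predictions[0].orientation == "lower_better"
    ordered = sorted(predictions, key=lambda p: (p.score if lower else -p.score, p.accession))
    m = math.ceil(fraction * len(ordered))
    boundary = ordered[m - 1].score
    if lower:
        return [p for p in ordered if p.score <= boundary]
    return [p for p in ordered if p.score >= boundary]


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0  # uniform columns carry no shape information
    return float(np.corrcoef(a, b)[0, 1])


def _alignment_similarity(q: np.ndarray, t: np.ndarray, min_overlap: int) -> tuple[float, int]:
    """Best mean column correlation over ungapped offsets; (similarity, offset)."""
    wq, wt = q.shape[0], t.shape[0]
    best, best_off = -np.inf, 0
    for off in range(-(wq - min_overlap), wt - min_overlap + 1):
        lo_q, hi_q = max(0, -off), min(wq, wt - off)
        if hi_q - lo_q < min_overlap:
            continue
        cols = [
            _column_correlation(q[k], t[k + off])
            for k in range(lo_q, hi_q)
        ]
        sim = float(np.mean(cols))
        if sim > best:
            best, best_off = sim, off
    return best, best_off


def match_pwm_to_library(
    query: PWM,
    library: list[PWM],
    min_overlap: int = 4,
    threshold: float = 0.75,
) -> PwmMatch | None:
    """Map a de-novo PWM to its best library accession, or None.

    Similarity is the mean Pearson correlation of aligned probability
    columns over the best ungapped offset, in either orientation; a match
    requires at least ``min_overlap`` aligned columns and similarity >=
    ``threshold``.  Ties break toward the lexicographically smaller
    accession.  Absence of a match is a value, not an error.
    """
    if not library:
        raise ValueError("empty library")
    best: PwmMatch | None = None
    for t in sorted(library, key=lambda p: p.accession):
        for orientation, qmat in (("+", query.probs), ("-", query.reverse_complement().probs)):
            sim, off = _alignment_similarity(qmat, t.probs, min_overlap)
            if not np.isfinite(sim):
                continue
            if best is None or sim > best.similarity + 1e-12:
                best = PwmMatch(t.accession, t.tf_name, sim, off, orientation)
    if best is None or best.similarity < threshold:
        return None
    return best


def map_discovery_predictions(
    motifs,
    library: list[PWM],
    min_overlap: int = 4,
    threshold: float = 0.75,
) -> list[MotifPrediction]:
    """Map discovered motifs onto library accessions as engine predictions.

    Unmapped motifs are dropped with a log entry; several de-novo motifs
    mapping to one accession merge, keeping the best (lowest) E-value.
    """
    by_acc: dict[str, MotifPrediction] = {}
    for m in motifs:
        hit = match_pwm_to_library(m.pwm, library, min_overlap=min_overlap, threshold=threshold)
        if hit is None:
            logger.info("de-novo motif %s (consensus %s) has no library match",
                        m.motif_id, m.pwm.consensus())
            continue
        score = m.e_value if m.e_value is not None else np.inf
        pred = MotifPrediction("discovery", hit.accession, float(score),
                               tf_name=hit.tf_name, source_id=m.motif_id)
        prev = by_acc.get(hit.accession)
        if prev is None or pred.score < prev.score:
            by_acc[hit.accession] = pred
    return sorted(by_acc.values(), key=lambda p: (p.score, p.accession))


def intersect_engines(retained: dict[str, list[MotifPrediction]]) -> list[ConsensusMotif]:
    """Accessions present in every engine's retained set, with their scores."""
    missing = [e for e in ENGINES if e not in retained]
    if missing:
        raise ValueError(f"missing engines: {missing}")
    per_engine: dict[str, dict[str, MotifPrediction]] = {}
    for engine in ENGINES:
        table: dict[str, MotifPrediction] = {}
        lower = ENGINE_ORIENTATION[engine] == "lower_better"
        for p in retained[engine]:
            prev = table.get(p.accession)
            if prev is None or (p.score < prev.score if lower else p.score > prev.score):
                table[p.accession] = p
        per_engine[engine] = table
    common = set.intersection(*(set(per_engine[e]) for e in ENGINES))
    out: list[ConsensusMotif] = []
    for acc in sorted(common):
        tf = next((per_engine[e][acc].tf_name for e in ENGINES if per_engine[e][acc].tf_name), "")
        out.append(ConsensusMotif(acc, tf, {e: per_engine[e][acc].score for e in ENGINES}))
    return out


@dataclass
class ContrastRow:
    accession: str
    engine: str
    test_score: float
    random_score: float | None
    better: str  # test | random | tie | absent


def contrast_test_vs_random(
    consensus: list[ConsensusMotif],
    random_retained: dict[str, list[MotifPrediction]],
    test_manifest: dict | None = None,
    random_manifest: dict | None = None,
) -> list[ContrastRow]:
    """Per consensus accession and engine, compare test vs random scores.

    When manifests are supplied they must agree on engine configuration
    (the runs should differ only in gene sets).  An accession the engine
    did not retain on random data is marked "absent".
    """
    if test_manifest is not None and random_manifest is not None:
        keys = set(test_manifest) & set(random_manifest) - {"gene_set", "seed", "n_genes", "genes"}
        for key in sorted(keys):
            if test_manifest[key] != random_manifest[key]:
                raise ValueError(f"engine config mismatch on {key!r}")
    rows: list[ContrastRow] = []
    for cm in consensus:
        for engine in ENGINES:
            lower = ENGINE_ORIENTATION[engine] == "lower_better"
            rand = next((p for p in random_retained.get(engine, []) if p.accession == cm.accession), None)
            test_score = cm.scores[engine]
            if rand is None:
                rows.append(ContrastRow(cm.accession, engine, test_score, None, "absent"))
                continue
            if test_score == rand.score:
                better = "tie"
            elif (test_score < rand.score) == lower:
                better = "test"
            else:
                better = "random"
            rows.append(ContrastRow(cm.accession, engine, test_score, rand.score, better))
    return rows
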