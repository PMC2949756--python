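"""TF-gene-set association by binding affinity and rank concordance.

For each library PWM, every promoter receives an occupancy-style affinity
(the sum over all windows and both strands of the exponentiated log-odds
score — a saturating-free TRAP-flavoured quantity that rewards both strong
single sites and multiple weaker ones).  Genes are ranked by affinity and,
independently, by a condition-specificity score (default: the log2
induction contrast that defines the gene set of interest).  An iterated
hypergeometric test then asks, over a grid of rank cutoffs (i, j), how
surprising the overlap of the top-i affinity genes with the top-j
specificity genes is; the minimum tail probability over the grid is the
association score.  Lower is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import PWM, PromoterSequence
from . import seqs as sq

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_GRID = (5, 10, 20, 50, 100, 200)


@dataclass
class AssociationResult:
    matrix_accession: str
    tf_name: str
    best_p: float
    best_cutoffs: tuple[int, int]
    overlap_k: int


def promoter_affinity(
    pwm: PWM,
    promoter: str | PromoterSequence,
    background: np.ndarray | None = None,
) -> float:
    """Occupancy-style affinity of one promoter for one PWM.

    Sum of ``exp(log-odds)`` over all windows on both strands; windows
    containing N contribute 0.  A promoter shorter than the PWM scores 0
    with a warning.
    """
    seq = promoter.sequence if isinstance(promoter, PromoterSequence) else promoter.upper()
    if len(seq) < pwm.width:
        logger.warning("promoter shorter than PWM %s; affinity 0", pwm.accession)
        return 0.0
    codes = sq.encode_set([seq])
    return float(_affinity_rows(pwm, codes, background)[0])


def _affinity_rows(pwm: PWM, codes: np.ndarray, background: np.ndarray | None) -> np.ndarray:
    lo = sq.extend_logp(pwm.log_odds(background))
    lo_rc = sq.extend_logp(pwm.reverse_complement().log_odds(background))
    total = np.zeros(codes.shape[0])
    for mat in (lo, lo_rc):
        scores = sq.window_scores(codes, mat, pwm.width)
        with np.errstate(over="ignore"):
            vals = np.exp(scores)
        vals[~np.isfinite(scores)] = 0.0
        total += vals.sum(axis=1)
    return total


def affinity_vector(
    pwm: PWM,
    promoters: list[PromoterSequence],
    background: np.ndarray | None = None,
) -> dict[str, float]:
    """Affinity of every promoter, 0-order background from the set itself."""
    seqs_ = [p.sequence for p in promoters]
    if background is None:
        background = sq.background_composition(seqs_)
    codes = sq.encode_set(seqs_)
    vals = _affinity_rows(pwm, codes, background)
    return {p.gene_id: float(v) for p, v in zip(promoters, vals)}


def hypergeometric_tail(k: int, n_draw: int, n_category: int, n_universe: int) -> float:
    """P(X >= k) for a hypergeometric draw of ``n_draw`` from a universe
    of ``n_universe`` containing ``n_category`` category members."""
    if not (0 <= k <= min(n_draw, n_category) and max(n_draw, n_category) <= n_universe):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, n_draw={n_draw}, "
            f"n_category={n_category}, n_universe={n_universe}"
        )
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, n_universe, n_category, n_draw))
    return min(p, 1.0)


def _ranked_genes(scores: dict[str, float]) -> list[str]:
    # descending score, ties broken lexicographically for determinism
    return sorted(scores, key=lambda g: (-scores[g], g))


def associate_tf(
    pwm: PWM,
    promoters: list[PromoterSequence],
    specificity: dict[str, float],
    cutoff_grid: tuple[int, ...] = DEFAULT_CUTOFF_GRID,
    background: np.ndarray | None = None,
    affinities: dict[str, float] | None = None,
    correct_by_grid: bool = False,
) -> AssociationResult:
    """Minimum hypergeometric tail over the cutoff grid for one PWM.

    Rank-based, hence invariant to monotone transforms of either score.
    ``affinities`` may be supplied to skip rescanning.  The minimum p is
    reported uncorrected by default; ``correct_by_grid`` applies a
    Bonferroni factor of the number of cutoff pairs searched.
    """
    genes = [p.gene_id for p in promoters]
    missing = [g for g in genes if g not in specificity]
    if missing:
        raise ValueError(f"specificity missing for genes: {missing[:5]}...")
    if affinities is None:
        affinities = affinity_vector(pwm, promoters, background=background)
    n = len(genes)
    grid = sorted({c for c in cutoff_grid if 1 <= c <= n})
    if not grid:
        raise ValueError("empty cutoff grid")

    aff_order = _ranked_genes({g: affinities[g] for g in genes})
    spec_order = _ranked_genes({g: specificity[g] for g in genes})
    aff_rank = {g: r for r, g in enumerate(aff_order)}
    spec_rank = {g: r for r, g in enumerate(spec_order)}

    best = (1.1, (0, 0), 0)
    for i in grid:
        top_aff = set(aff_order[:i])
        for j in grid:
            k = sum(1 for g in spec_order[:j] if g in top_aff)
            p = hypergeometric_tail(k, i, j, n)
            if p < best[0]:
                best = (p, (i, j), k)
    best_p = best[0] * len(grid) ** 2 if correct_by_grid else best[0]
    return AssociationResult(pwm.accession, pwm.tf_name, float(min(best_p, 1.0)),
                             best[1], best[2])


def associate_library(
    library: list[PWM],
    promoters: list[PromoterSequence],
    specificity: dict[str, float],
    cutoff_grid: tuple[int, ...] = DEFAULT_CUTOFF_GRID,
) -> list[AssociationResult]:
    """Associate every library PWM with the specificity ranking.

    One shared 0-order background (the promoter set composition) is used
    for all affinity scans.  Results are sorted by best_p ascending.
    """
    background = sq.background_composition([p.sequence for p in promoters])
    results = [
        associate_tf(pwm, promoters, specificity, cutoff_grid=cutoff_grid,
                     background=background)
        for pwm in library
    ]
    results.sort(key=lambda r: (r.best_p, r.matrix_accession))
    return results
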