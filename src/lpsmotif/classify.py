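"""Phenotype classification of LPS-stimulated macrophage genes.

The filtering paradigm works on condition averages per probe: with
``X = N_avg`` (untreated), ``Y = (N+L)_avg`` (naive + 4 h LPS) and
``Z = (T+L)_avg`` (24 h LPS then 4 h re-stimulation),

* a *pro-inflammatory* (tolerizable) probe has ``Y/X > 1``, ``Z/Y < 1`` and
  a Welch two-tailed t-test p-value below ``alpha`` for the naive-vs-tolerant
  contrast;
* an *antibacterial* (non-tolerizable) probe has ``Y/X > 1``, ``Z/Y > 1``
  (strictly) and p below ``alpha``;
* everything else is *unclassified*.

A relaxed two-fold signature (>= 2-fold induction N -> N+L and >= 2-fold
repression N+L -> T+L, no p-value threshold) feeds literature-target
validation, and a four-condition variant compares (N+L)/N against (T+L)/T
fold changes to flag "tolerizable" genes in an independent dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, ExpressionRecord, normalize_symbol

logger = logging.getLogger(__name__)

PRO = "pro_inflammatory"
ANTI = "antibacterial"
UNCLASSIFIED = "unclassified"

Contrast = Literal["N_vs_TL", "N_vs_NL"]


@dataclass
class PhenotypeCall:
    """Per-probe classification outcome with the quantities it rests on."""

    probe_id: str
    gene_symbol: str
    n_avg: float
    nl_avg: float
    tl_avg: float
    r1: float | None  # (N+L)/N
    r2: float | None  # (T+L)/(N+L)
    p_value: float | None
    label: str
    reason: str = ""


@dataclass
class RelativeExpressionProfile:
    """Condition averages scaled so the global maximum N average maps to 1."""

    gene_symbol: str
    rel_n: float
    rel_nl: float
    rel_tl: float


@dataclass
class ClassificationResult:
    calls: list[PhenotypeCall]
    pro_genes: list[str]
    anti_genes: list[str]
    pro_probe_ids: list[str]
    anti_probe_ids: list[str]

    @property
    def counts(self) -> dict[str, int]:
        """Probe-level and symbol-collapsed set sizes."""
        return {
            "pro_probes": len(self.pro_probe_ids),
            "anti_probes": len(self.anti_probe_ids),
            "pro_genes": len(self.pro_genes),
            "anti_genes": len(self.anti_genes),
        }


def condition_averages(record: ExpressionRecord) -> tuple[float, float, float]:
    """Arithmetic means of the N, N+L and T+L replicates."""
    for cond in ("N", "NL", "TL"):
        if cond not in record.values:
            raise KeyError(f"probe {record.probe_id!r}: missing condition {cond!r}")
    return record.mean("N"), record.mean("NL"), record.mean("TL")


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-tailed p-value of the unequal-variance (Welch) t-test.

    Degenerate conventions: when both groups have zero variance the p-value
    is 1 for equal means (no evidence of difference) and 0 for unequal means
    (the limit of the t statistic as the pooled standard error vanishes).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def classify_gene(
    record: ExpressionRecord,
    alpha: float = 0.05,
    contrast: Contrast = "N_vs_TL",
) -> PhenotypeCall:
    """Classify one probe as pro-inflammatory, antibacterial or neither."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n_avg, nl_avg, tl_avg = condition_averages(record)
    base = PhenotypeCall(record.probe_id, record.gene_symbol, n_avg, nl_avg, tl_avg,
                         None, None, None, UNCLASSIFIED)
    if n_avg == 0.0 or nl_avg == 0.0:
        base.reason = "zero denominator in ratio"
        return base
    r1 = nl_avg / n_avg
    r2 = tl_avg / nl_avg
    other = record.values["TL"] if contrast == "N_vs_TL" else record.values["NL"]
    p = welch_t_test(record.values["N"], other)
    label, reason = UNCLASSIFIED, ""
    if r1 > 1.0 and p < alpha:
        if r2 < 1.0:
            label = PRO
        elif r2 > 1.0:
            label = ANTI
        else:
            reason = "T+L equals N+L (strict inequality required)"
    elif r1 <= 1.0:
        reason = "no induction in N+L"
    else:
        reason = f"p-value {p:.3g} >= alpha"
    return PhenotypeCall(record.probe_id, record.gene_symbol, n_avg, nl_avg, tl_avg,
                         r1, r2, p, label, reason)


def classify_matrix(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    contrast: Contrast = "N_vs_TL",
    p_adjust: str | None = None,
) -> ClassificationResult:
    """Classify every probe and collapse the hit lists to gene symbols.

    Gene-level membership follows the representative probe per symbol (the
    one with the highest overall mean intensity), so the probe-level and
    symbol-level counts can differ; both are reported.  ``p_adjust="bh"``
    applies a Benjamini-Hochberg correction across probes before the alpha
    threshold; the default applies none.
    """
    if p_adjust not in (None, "bh"):
        raise ValueError("p_adjust must be None or 'bh'")
    calls = [classify_gene(rec, alpha=alpha, contrast=contrast) for rec in matrix]
    if p_adjust == "bh":
        idx = [i for i, c in enumerate(calls) if c.p_value is not None]
        adjusted = stats.false_discovery_control([calls[i].p_value for i in idx])
        for i, q in zip(idx, adjusted):
            c = calls[i]
            c.p_value = float(q)
            if c.label in (PRO, ANTI) and c.p_value >= alpha:
                c.label = UNCLASSIFIED
                c.reason = f"BH-adjusted p {c.p_value:.3g} >= alpha"
    pro_probes = [c.probe_id for c in calls if c.label == PRO]
    anti_probes = [c.probe_id for c in calls if c.label == ANTI]

    collapsed = matrix.collapse_by_symbol()
    call_by_probe = {c.probe_id: c for c in calls}
    pro_genes = [r.gene_symbol for r in collapsed if call_by_probe[r.probe_id].label == PRO]
    anti_genes = [r.gene_symbol for r in collapsed if call_by_probe[r.probe_id].label == ANTI]
    result = ClassificationResult(calls, pro_genes, anti_genes, pro_probes, anti_probes)
    logger.info("classification counts: %s", result.counts)
    return result


def _twofold_pass(record: ExpressionRecord, fold: float) -> bool:
    n_avg, nl_avg, tl_avg = condition_averages(record)
    if n_avg == 0.0 or tl_avg == 0.0:
        return False
    return nl_avg / n_avg >= fold and nl_avg / tl_avg >= fold


@dataclass
class TwofoldSignature:
    probe_ids: list[str]
    genes: list[str]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_keys(self) -> set[str]:
        return {normalize_symbol(g) for g in self.genes}


def twofold_signature(matrix: ExpressionMatrix, fold: float = 2.0) -> TwofoldSignature:
    """Genes with >= fold induction N -> N+L and >= fold repression N+L -> T+L.

    Boundaries are inclusive (exactly two-fold passes); no p-value filter.
    Probes with zero denominators are excluded. Gene membership follows the
    representative probe per symbol.
    """
    probe_ids = [rec.probe_id for rec in matrix if _twofold_pass(rec, fold)]
    passing = set(probe_ids)
    genes = [r.gene_symbol for r in matrix.collapse_by_symbol() if r.probe_id in passing]
    logger.info("two-fold signature: %d probes, %d genes (fold=%g)",
                len(probe_ids), len(genes), fold)
    return TwofoldSignature(probe_ids, genes)


def relative_profiles(
    matrix: ExpressionMatrix, genes: Iterable[str]
) -> list[RelativeExpressionProfile]:
    """Condition averages for ``genes`` divided by the global maximum N average.

    The normalization anchor is computed over the *full* matrix, so the gene
    with the highest untreated expression has ``rel_n == 1``.
    """
    n_max = float(matrix.means("N").max())
    if n_max <= 0:
        raise ValueError("matrix has no positive N-condition intensity")
    collapsed = matrix.collapse_by_symbol()
    by_key = {normalize_symbol(r.gene_symbol): r for r in collapsed}
    profiles: list[RelativeExpressionProfile] = []
    for gene in genes:
        rec = by_key.get(normalize_symbol(gene))
        if rec is None:
            logger.warning("relative_profiles: gene %r absent from matrix, skipped", gene)
            continue
        n_avg, nl_avg, tl_avg = condition_averages(rec)
        profiles.append(RelativeExpressionProfile(
            rec.gene_symbol, n_avg / n_max, nl_avg / n_max, tl_avg / n_max))
    return profiles


def cross_dataset_pattern(
    matrix: ExpressionMatrix, genes: Iterable[str]
) -> tuple[dict[str, bool], int]:
    """Tolerizability check on a four-condition (N, N+L, T, T+L) layout.

    A gene is flagged tolerizable iff ``(N+L)/N > 1`` (induced by the first
    stimulation) and ``(T+L)/T < (N+L)/N`` strictly (the re-stimulation fold
    change falls short of the naive one).  Genes with zero denominators are
    excluded with a warning.
    """
    for cond in ("N", "NL", "T", "TL"):
        if cond not in matrix.condition_design:
            raise ValueError(f"cross-dataset check needs condition {cond!r}")
    collapsed = matrix.collapse_by_symbol()
    by_key = {normalize_symbol(r.gene_symbol): r for r in collapsed}
    flags: dict[str, bool] = {}
    for gene in genes:
        rec = by_key.get(normalize_symbol(gene))
        if rec is None:
            logger.warning("cross_dataset_pattern: gene %r absent, skipped", gene)
            continue
        n, nl, t = rec.mean("N"), rec.mean("NL"), rec.mean("T")
        if n == 0.0 or t == 0.0:
            logger.warning("cross_dataset_pattern: gene %r has zero denominator", gene)
            continue
        fc_first = nl / n
        fc_second = rec.mean("TL") / t
        flags[gene] = fc_first > 1.0 and fc_second < fc_first
    return flags, sum(flags.values())


def random_gene_pattern_null(
    matrix: ExpressionMatrix,
    set_size: int = 18,
    n_sets: int = 10,
    seed: int = 0,
    fold: float = 2.0,
) -> list[int]:
    """Pattern counts for seeded random gene sets (the background control).

    For each of ``n_sets`` random draws of ``set_size`` genes (without
    replacement within a set), count how many pass the two-fold
    pro-inflammatory pattern.  With the pattern rare in the matrix these
    counts should sit near zero, which is what makes a perfect score on a
    curated target list informative.
    """
    collapsed = matrix.collapse_by_symbol()
    n_genes = len(collapsed.records)
    if set_size > n_genes:
        raise ValueError(f"set_size {set_size} exceeds matrix gene count {n_genes}")
    rng = np.random.default_rng(seed)
    passing = {r.probe_id for r in collapsed if _twofold_pass(r, fold)}
    counts: list[int] = []
    for _ in range(n_sets):
        idx = rng.choice(n_genes, size=set_size, replace=False)
        counts.append(sum(1 for i in idx if collapsed.records[i].probe_id in passing))
    return counts
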