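"""Motif-expression linear modelling: the transcription contribution score.

Each motif (a fixed-size word or a library PWM) is mapped onto the promoter
set to give an occurrence-count matrix.  A linear model of an expression
response (default: the log2 tolerance contrast of the gene set) on the
counts of a random motif subset is fitted by least squares; iterating over
many seeded subsets, each motif accumulates the absolute value of its
standardized coefficient.  The transcription contribution score (TCS) is
that accumulation normalized by how often the motif was sampled, and the
sign of the mean raw coefficient labels the motif stimulatory or
inhibitory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import PWM, PromoterSequence
from . import seqs as sq

logger = logging.getLogger(__name__)


@dataclass
class MotifCountMatrix:
    genes: list[str]
    motifs: list[str]
    counts: np.ndarray  # (n_genes, n_motifs) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.motifs)):
            raise ValueError("count matrix dimensions inconsistent with labels")
        if np.any(self.counts < 0):
            raise ValueError("negative occurrence count")


@dataclass
class LinearFit:
    coefficients: np.ndarray
    intercept: float
    residual_ss: float
    confounded: list[int]
    used_ridge: bool


@dataclass
class TcsResult:
    motif_id: str
    tcs: float
    sign: str  # stimulatory | inhibitory | indeterminate
    times_sampled: int
    mean_coefficient: float


def count_word_occurrences(word: str, promoter: str | PromoterSequence, both_strands: bool = True) -> int:
    """Overlapping occurrences of an exact word, counted once per strand.

    The reverse strand is scanned as the reverse complement of the word on
    the forward sequence, so a palindromic word at one location counts
    twice.  N never matches.
    """
    seq = promoter.sequence if isinstance(promoter, PromoterSequence) else promoter.upper()
    word = word.upper()
    if not set(word) <= set("ACGT"):
        raise ValueError(f"motif word {word!r} must be over ACGT")
    if len(word) > len(seq):
        logger.warning("motif %r longer than promoter (length %d)", word, len(seq))
        return 0

    def occ(w: str) -> int:
        count, start = 0, 0
        while True:
            i = seq.find(w, start)
            if i < 0:
                return count
            count += 1
            start = i + 1

    total = occ(word)
    if both_strands:
        total += occ(sq.revcomp(word))
    return total


def count_pwm_occurrences(
    pwm: PWM,
    promoter: str | PromoterSequence,
    background: np.ndarray | None = None,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> int:
    """Windows whose log-odds score reaches ``rel_threshold`` of the maximum."""
    seq = promoter.sequence if isinstance(promoter, PromoterSequence) else promoter.upper()
    if pwm.width > len(seq):
        logger.warning("PWM %s wider than promoter (length %d)", pwm.accession, len(seq))
        return 0
    codes = sq.encode_set([seq])
    lo = pwm.log_odds(background)
    threshold = rel_threshold * lo.max(axis=1).sum()
    logp = sq.extend_logp(lo)
    scores = sq.window_scores(codes, logp, pwm.width)
    n = int(np.sum(scores >= threshold))
    if both_strands:
        lo_rc = pwm.reverse_complement().log_odds(background)
        scores_rc = sq.window_scores(codes, sq.extend_logp(lo_rc), pwm.width)
        n += int(np.sum(scores_rc >= threshold))
    return n


def count_motif_occurrences(motif, promoter, both_strands: bool = True,
                            background: np.ndarray | None = None,
                            rel_threshold: float = 0.8) -> int:
    """Dispatch on motif type: exact word (str) or PWM."""
    if isinstance(motif, PWM):
        return count_pwm_occurrences(motif, promoter, background=background,
                                     rel_threshold=rel_threshold, both_strands=both_strands)
    return count_word_occurrences(str(motif), promoter, both_strands=both_strands)


def word_universe(promoters: list[PromoterSequence], k: int = 8, min_count: int = 3) -> list[str]:
    """All k-mers occurring at least ``min_count`` times in the set (both strands)."""
    if not 4 <= k <= 12:
        raise ValueError("word size must be between 4 and 12")
    codes = sq.encode_set([p.sequence for p in promoters])
    total = np.zeros(4 ** k, dtype=np.int64)
    vals, valid = sq.window_word_codes(codes, k)
    total += np.bincount(vals[valid], minlength=4 ** k)
    rc_codes = sq.COMP[codes][:, ::-1]
    rvals, rvalid = sq.window_word_codes(rc_codes, k)
    total += np.bincount(rvals[rvalid], minlength=4 ** k)
    keep = np.flatnonzero(total >= min_count)
    return [sq.word_from_code(int(c), k) for c in keep]


def build_count_matrix(
    promoters: list[PromoterSequence],
    motifs,
    both_strands: bool = True,
    background: np.ndarray | None = None,
    rel_threshold: float = 0.8,
) -> MotifCountMatrix:
    """Occurrence counts of every motif in every promoter.

    Word universes are counted with a single vectorized pass; PWMs are
    scanned promoter by promoter.  The 0-order background for PWM
    thresholds defaults to the composition of the promoter set itself.
    """
    genes = [p.gene_id for p in promoters]
    motif_list = list(motifs)
    if background is None:
        background = sq.background_composition([p.sequence for p in promoters])

    if motif_list and all(isinstance(m, str) for m in motif_list):
        k = len(motif_list[0])
        if all(len(m) == k for m in motif_list) and k <= 12:
            return _word_count_matrix(promoters, motif_list, k, both_strands)

    counts = np.zeros((len(promoters), len(motif_list)), dtype=np.int64)
    ids = []
    for j, m in enumerate(motif_list):
        ids.append(m.accession if isinstance(m, PWM) else str(m))
        for i, p in enumerate(promoters):
            counts[i, j] = count_motif_occurrences(
                m, p, both_strands=both_strands,
                background=background, rel_threshold=rel_threshold)
    return MotifCountMatrix(genes, ids, counts)


def _word_count_matrix(promoters, words: list[str], k: int, both_strands: bool) -> MotifCountMatrix:
    codes = sq.encode_set([p.sequence for p in promoters])
    word_codes = np.array([
        sum(sq.BASES.index(c) * 4 ** (k - 1 - i) for i, c in enumerate(w.upper()))
        for w in words
    ])
    n = len(promoters)
    per_gene = np.zeros((n, 4 ** k), dtype=np.int32)
    vals, valid = sq.window_word_codes(codes, k)
    for i in range(n):
        per_gene[i] += np.bincount(vals[i][valid[i]], minlength=4 ** k).astype(np.int32)
    if both_strands:
        rc_codes = sq.COMP[codes][:, ::-1]
        rvals, rvalid = sq.window_word_codes(rc_codes, k)
        for i in range(n):
            per_gene[i] += np.bincount(rvals[i][rvalid[i]], minlength=4 ** k).astype(np.int32)
    counts = per_gene[:, word_codes]
    return MotifCountMatrix([p.gene_id for p in promoters], list(words), counts)


def fit_linear_model(counts: MotifCountMatrix | np.ndarray, response) -> LinearFit:
    """Least-squares fit of the response on motif occurrence counts.

    Constant predictor columns are confounded with the intercept; they are
    excluded from the solve, reported with coefficient 0 and flagged.  When
    the design is singular or under-determined a small ridge
    (``lambda = 1e-6 * trace(X'X)``) stabilizes the solve and is flagged.
    """
    X = counts.counts if isinstance(counts, MotifCountMatrix) else np.asarray(counts)
    X = X.astype(float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("response length does not match gene count")

    stds = X.std(axis=0)
    confounded = [int(j) for j in np.flatnonzero(stds == 0.0)]
    active = np.flatnonzero(stds > 0.0)
    coefs = np.zeros(p)
    Xa = np.column_stack([np.ones(n), X[:, active]])
    used_ridge = False
    if Xa.shape[0] <= Xa.shape[1] or np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        used_ridge = True
        G = Xa.T @ Xa
        lam = 1e-6 * np.trace(G)
        beta = np.linalg.solve(G + lam * np.eye(G.shape[0]), Xa.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    coefs[active] = beta[1:]
    resid = y - Xa @ beta
    return LinearFit(coefs, float(beta[0]), float(resid @ resid), confounded, used_ridge)


def random_response(range_min: float, range_max: float, n: int, seed: int = 0) -> np.ndarray:
    """Seeded uniform draws in [range_min, range_max] (the random-gene response)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if range_min > range_max:
        raise ValueError("range_min must be <= range_max")
    rng = np.random.default_rng(seed)
    return rng.uniform(range_min, range_max, size=n)


def run_tcs(
    promoters: list[PromoterSequence],
    response,
    motif_universe=None,
    k: int = 8,
    min_count: int = 3,
    subset_size: int = 20,
    n_iterations: int = 500,
    seed: int = 0,
    normalization: str = "mean",
    count_matrix: MotifCountMatrix | None = None,
) -> list[TcsResult]:
    """Iterated random-subset regression producing one TCS per motif.

    ``motif_universe`` may be a list of words, a list of PWMs (their
    accessions become the motif ids) or None, in which case all k-mers with
    at least ``min_count`` hits in the promoter set are used.  Each of
    ``n_iterations`` seeded draws fits ``subset_size`` motifs; sampled
    motifs accumulate ``|standardized coefficient|``.  ``normalization``:
    "mean" (accumulated / times sampled, the default — insensitive to how
    often a motif happens to be drawn) or "sum" (raw cumulative score).
    Results are sorted by TCS descending.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if normalization not in ("mean", "sum"):
        raise ValueError("normalization must be 'mean' or 'sum'")
    y = np.asarray(response, dtype=float)
    if count_matrix is None:
        if motif_universe is None:
            motif_universe = word_universe(promoters, k=k, min_count=min_count)
        count_matrix = build_count_matrix(promoters, motif_universe)
    p = len(count_matrix.motifs)
    if subset_size > p:
        raise ValueError(f"subset_size {subset_size} exceeds universe size {p}")
    if y.shape[0] != len(count_matrix.genes):
        raise ValueError("response length does not match promoter count")

    sy = y.std()
    rng = np.random.default_rng(seed)
    acc = np.zeros(p)
    raw_sum = np.zeros(p)
    times = np.zeros(p, dtype=int)
    X = count_matrix.counts.astype(float)
    col_std = X.std(axis=0)
    for _ in range(n_iterations):
        idx = rng.choice(p, size=subset_size, replace=False)
        fit = fit_linear_model(X[:, idx], y)
        std_coef = fit.coefficients * col_std[idx] / sy if sy > 0 else np.zeros(subset_size)
        acc[idx] += np.abs(std_coef)
        raw_sum[idx] += fit.coefficients
        times[idx] += 1

    results: list[TcsResult] = []
    scale = max(np.abs(raw_sum).max(), 1e-300)
    for j, mid in enumerate(count_matrix.motifs):
        if times[j] == 0:
            results.append(TcsResult(mid, 0.0, "indeterminate", 0, 0.0))
            continue
        tcs = acc[j] / times[j] if normalization == "mean" else acc[j]
        mean_raw = raw_sum[j] / times[j]
        if abs(mean_raw) <= 1e-12 * scale:
            sign = "indeterminate"
        else:
            sign = "stimulatory" if mean_raw > 0 else "inhibitory"
        results.append(TcsResult(mid, float(tcs), sign, int(times[j]), float(mean_raw)))
    results.sort(key=lambda r: (-r.tcs, r.motif_id))
    return results
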