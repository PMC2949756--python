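"""De-novo motif discovery by expectation–maximization under ZOOPS.

The model is a two-component finite mixture over promoter sequences: with
probability ``gamma`` a sequence contains exactly one motif occurrence at a
uniformly chosen admissible position (on either strand when ``revcomp`` is
on), and with probability ``1 - gamma`` it is pure 0-order background.  The
E-step computes per-window site posteriors and the per-sequence occurrence
posterior; the M-step re-estimates the PWM columns and ``gamma``.  The EM
objective (the data log-likelihood ratio against background-only, ``llr``)
is non-decreasing every iteration.

Multiple motifs are extracted sequentially: after each motif converges, its
best site per sequence (posterior > 0.5) is hard-masked with N before the
next search.  Statistical calibration uses a Monte-Carlo E-value: the fit is
repeated on dinucleotide-shuffled sequences and the observed ``llr`` is
ranked among the null refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import PWM, PromoterSequence
from . import seqs as sq

logger = logging.getLogger(__name__)

MIN_WIDTH = 4
DEFAULT_WIDTH_GRID = (6, 8, 10, 12, 15)

#: EM configuration used when refitting on shuffled sequences for E-values.
#: Deliberately cheaper than the observed fit; see the methods note.
NULL_REFIT_PARAMS = dict(n_starts=5, start_iters=1, n_refine=1, max_iter=15, tol=1e-3)


@dataclass
class SiteCall:
    """Maximum-posterior site for one sequence."""

    seq_index: int
    gene_id: str
    offset: int
    strand: str
    probability: float


@dataclass
class DiscoveredMotif:
    motif_id: str
    pwm: PWM
    llr: float
    gamma: float
    sites: list[SiteCall]
    loglik_history: list[float]
    revcomp: bool
    e_value: float | None = None
    #: per-sequence posterior probability of containing a site (ZOOPS: <= 1)
    occurrence_posteriors: list[float] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pwm.width

    def consensus(self) -> str:
        return self.pwm.consensus()


def _as_strings(sequences) -> tuple[list[str], list[str]]:
    strs, ids = [], []
    for i, s in enumerate(sequences):
        if isinstance(s, PromoterSequence):
            strs.append(s.sequence)
            ids.append(s.gene_id)
        else:
            strs.append(str(s).upper())
            ids.append(f"seq{i}")
    return strs, ids


def _seed_pwm(word_code: int, width: int, match: float = 0.55) -> np.ndarray:
    probs = np.full((width, 4), (1.0 - match) / 3.0)
    for k in reversed(range(width)):
        probs[k, word_code % 4] = match
        word_code //= 4
    return probs


def _neighbor_words(word: int, width: int):
    """All 3*width single-mismatch neighbours of a base-4 word code."""
    for k in range(width):
        shift = 4 ** (width - 1 - k)
        cur = (word // shift) % 4
        stem = word - cur * shift
        for b in range(4):
            if b != cur:
                yield stem + b * shift


def _top_seed_words(codes: np.ndarray, width: int, n_starts: int, revcomp: bool) -> list[int]:
    """Candidate start words: width-mers ranked by 1-mismatch neighbourhood count.

    Instances of a real motif scatter around its consensus, diluting exact
    word counts, so candidates (pre-filtered by exact count) are re-ranked
    by the total count of their Hamming-1 neighbourhood; seeds within one
    mismatch of an already chosen seed are skipped to keep starts diverse.
    Deterministic; ties break toward the lexicographically smaller word.
    """
    vals, valid = sq.window_word_codes(codes, width)
    all_vals = [vals[valid]]
    if revcomp:
        rc_codes = sq.COMP[codes][:, ::-1]
        rvals, rvalid = sq.window_word_codes(rc_codes, width)
        all_vals.append(rvals[rvalid])
    flat = np.concatenate(all_vals)
    if flat.size == 0:
        return []
    words, counts = np.unique(flat, return_counts=True)
    order = np.lexsort((words, -counts))
    n_cand = min(len(words), max(4 * n_starts, 200))
    table = dict(zip(words.tolist(), counts.tolist()))
    cand = [int(words[i]) for i in order[:n_cand]]

    def neighbourhood_count(wd: int) -> int:
        return table.get(wd, 0) + sum(table.get(nb, 0) for nb in _neighbor_words(wd, width))

    cand.sort(key=lambda wd: (-neighbourhood_count(wd), wd))
    picked: list[int] = []
    picked_set: set[int] = set()
    for wd in cand:
        if wd in picked_set or any(nb in picked_set for nb in _neighbor_words(wd, width)):
            continue
        picked.append(wd)
        picked_set.add(wd)
        if len(picked) >= n_starts:
            break
    return picked


class _ZoopsState:
    """One EM state: PWM probabilities, occurrence prior, score caches.

    Window validity (no N anywhere in the window) is fixed by the input, so
    it is computed once; scoring runs in float32 with the N score column set
    to 0 and invalid windows forced to -inf afterwards.
    """

    def __init__(self, codes, lengths, width, bg, revcomp, pseudocount):
        self.codes = codes
        self.codes64 = codes.astype(np.int64)
        self.width = width
        self.bg = bg
        self.log_bg = np.log(bg)
        self.revcomp = revcomp
        self.pseudocount = pseudocount
        self.bg_win = sq.bg_window_scores(codes, self.log_bg, width).astype(np.float32)
        _, self.valid = sq.window_word_codes(codes, width)
        n_strands = 2 if revcomp else 1
        self.M = n_strands * self.valid.sum(axis=1)
        self.gamma = 0.5
        self.probs: np.ndarray | None = None
        self.llr = -np.inf

    def _scores(self, probs: np.ndarray) -> np.ndarray:
        """Motif-vs-background log-likelihood ratio per window (float32)."""
        w = self.width
        logp = np.zeros((w, 5), dtype=np.float32)
        logp[:, :4] = np.log(np.clip(probs, 1e-12, None))
        n, L = self.codes.shape
        m = L - w + 1
        s = np.zeros((n, m), dtype=np.float32)
        for k in range(w):
            s += logp[k][self.codes[:, k : k + m]]
        s -= self.bg_win
        s[~self.valid] = -np.inf
        return s

    def iterate(self) -> float:
        """One E+M step; returns the post-E-step log-likelihood ratio."""
        fwd = self._scores(self.probs)
        parts = [fwd]
        if self.revcomp:
            parts.append(self._scores(self.probs[::-1, ::-1]))
        allm = np.concatenate(parts, axis=1)
        M = self.M
        with np.errstate(invalid="ignore"):
            mx = allm.max(axis=1).astype(np.float64)
            ok = np.isfinite(mx)
            e = np.exp(allm - np.where(ok, mx, 0.0)[:, None].astype(np.float32))
            S = e.sum(axis=1, dtype=np.float64)
        # log Z_i = log[(1-gamma) + (gamma / M_i) sum_j exp(llr_ij)]
        lse = np.where(ok, mx + np.log(np.maximum(S, 1e-300)), -np.inf)
        log_site = np.where(M > 0, np.log(self.gamma) - np.log(np.maximum(M, 1)) + lse, -np.inf)
        logZ = np.logaddexp(np.log1p(-self.gamma), log_site)
        # site posterior = (gamma/M) exp(llr) / Z, computed via the shifted exps
        scale = np.where(
            ok,
            np.exp(np.log(self.gamma) - np.log(np.maximum(M, 1)) + mx - logZ),
            0.0,
        )
        post = e * scale[:, None].astype(np.float32)
        # analytically <= 1; float32 rounding can overshoot by ~1e-7
        self._occupancy = np.clip(post.sum(axis=1, dtype=np.float64), 0.0, 1.0)

        m = fwd.shape[1]
        post_fwd = post[:, :m].astype(np.float64)
        post_rev = post[:, m:].astype(np.float64) if self.revcomp else None
        self._mstep(post_fwd, post_rev)
        self.gamma = float(np.clip(self._occupancy.mean(), 1e-6, 1.0 - 1e-6))
        self.llr = float(logZ.sum())
        self._last_post = (post_fwd, post_rev)
        return self.llr

    def _mstep(self, post_fwd, post_rev) -> None:
        w = self.width
        n, L = self.codes.shape
        m = L - w + 1
        counts = np.zeros((w, 4))
        for k in range(w):
            c = np.bincount(
                self.codes64[:, k : k + m].ravel(),
                weights=post_fwd.ravel(),
                minlength=5,
            )[:4]
            counts[k] += c
            if post_rev is not None:
                c2 = np.bincount(
                    self.codes64[:, w - 1 - k : w - 1 - k + m].ravel(),
                    weights=post_rev.ravel(),
                    minlength=5,
                )[:4]
                counts[k] += c2[[3, 2, 1, 0]]
        counts += self.pseudocount * self.bg
        self.probs = counts / counts.sum(axis=1, keepdims=True)

    def best_sites(self, gene_ids) -> list[SiteCall]:
        """Maximum-posterior site per sequence.

        The site-location posterior sums both strand contributions at one
        offset (a palindromic motif splits its mass between strands); the
        reported strand is the larger contributor.
        """
        post_fwd, post_rev = self._last_post
        sites: list[SiteCall] = []
        for i in range(post_fwd.shape[0]):
            pf = post_fwd[i]
            if pf.size == 0:
                continue
            combined = pf if post_rev is None else pf + post_rev[i]
            off = int(combined.argmax())
            prob = float(min(combined[off], 1.0))
            if prob <= 0.0:
                continue
            strand = "+"
            if post_rev is not None and post_rev[i][off] > pf[off]:
                strand = "-"
            sites.append(SiteCall(i, gene_ids[i], off, strand, prob))
        return sites


def em_zoops(
    sequences,
    width: int,
    background: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    revcomp: bool = True,
    n_starts: int = 50,
    start_iters: int = 1,
    n_refine: int = 1,
    init_pwm: np.ndarray | PWM | None = None,
    pseudocount: float = 1e-3,
    motif_id: str = "DENOVO1",
) -> DiscoveredMotif:
    """Fit one ZOOPS motif of fixed ``width`` by EM.

    Starting points are the ``n_starts`` width-mers with the highest
    1-mismatch neighbourhood counts (both strands when ``revcomp``); every
    start runs ``start_iters`` EM iterations, the best ``n_refine`` by
    short-run likelihood continue to convergence, and the best final
    likelihood wins, which makes the whole fit deterministic.  ``init_pwm``
    bypasses seeding (used for hand-checked single iterations).  Raises
    ``ValueError`` when ``width < 4`` or fewer than two sequences have an
    admissible window.
    """
    if width < MIN_WIDTH:
        raise ValueError(f"motif width must be >= {MIN_WIDTH}, got {width}")
    strs, gene_ids = _as_strings(sequences)
    if len(strs) < 2:
        raise ValueError("need at least 2 sequences")
    codes = sq.encode_set(strs)
    _, valid = sq.window_word_codes(codes, width)
    n_usable = int((valid.sum(axis=1) > 0).sum())
    if n_usable < 2:
        raise ValueError(
            f"fewer than 2 sequences contain a window of {width} non-N characters"
        )
    bg = (
        sq.background_composition(strs)
        if background is None
        else np.asarray(background, dtype=float)
    )
    lengths = np.array([len(s) for s in strs])

    def fresh_state() -> _ZoopsState:
        return _ZoopsState(codes, lengths, width, bg, revcomp, pseudocount)

    if init_pwm is not None:
        start_probs = [init_pwm.probs if isinstance(init_pwm, PWM) else np.asarray(init_pwm, float)]
    else:
        words = _top_seed_words(codes, width, n_starts, revcomp)
        if not words:
            raise ValueError("no admissible seed words")
        start_probs = [_seed_pwm(wd, width) for wd in words]

    def run_to_convergence(st: _ZoopsState, history: list[float]) -> None:
        for _ in range(max_iter):
            prev = st.llr
            st.iterate()
            history.append(st.llr)
            if st.llr < prev - 1e-6 * (1.0 + abs(prev)):
                logger.warning("EM objective decreased: %.6f -> %.6f", prev, st.llr)
            if st.llr - prev < tol:
                break

    # short-run every start, then refine the best few to convergence; a
    # diffuse high-occupancy pattern can out-score a genuine motif after a
    # single iteration, so the final likelihood decides among the leaders
    scored: list[_ZoopsState] = []
    for probs in start_probs:
        st = fresh_state()
        st.probs = np.asarray(probs, dtype=float)
        for _ in range(max(1, start_iters)):
            st.iterate()
        scored.append(st)
    scored.sort(key=lambda st: -st.llr)
    leaders = scored[: max(1, n_refine)] if init_pwm is None else scored[:1]

    state, history = None, []
    for st in leaders:
        h = [st.llr]
        if max_iter > 0:
            run_to_convergence(st, h)
        if state is None or st.llr > state.llr:
            state, history = st, h

    pwm = PWM(motif_id, "", state.probs)
    return DiscoveredMotif(
        motif_id=motif_id,
        pwm=pwm,
        llr=state.llr,
        gamma=state.gamma,
        sites=state.best_sites(gene_ids),
        loglik_history=history,
        revcomp=revcomp,
        occurrence_posteriors=[float(x) for x in state._occupancy],
    )


def motif_e_value(
    motif: DiscoveredMotif,
    sequences,
    n_shuffles: int = 20,
    seed: int = 0,
    n_widths: int = 1,
    refit_params: dict | None = None,
) -> float:
    """Monte-Carlo E-value of a fitted motif.

    The motif's log-likelihood ratio is ranked among refits on
    dinucleotide-shuffled copies of the input; the add-one estimate
    ``(1 + #better) / (n_shuffles + 1)`` is Bonferroni-scaled by the number
    of candidate widths tried, so the attainable floor is
    ``n_widths / (n_shuffles + 1)``.  Deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    params = dict(NULL_REFIT_PARAMS)
    if refit_params:
        params.update(refit_params)
    strs, _ = _as_strings(sequences)
    exceed = 0
    for s in range(n_shuffles):
        rng = np.random.default_rng([seed, s])
        shuffled = [sq.dinucleotide_shuffle(x, rng) for x in strs]
        try:
            null = em_zoops(
                shuffled, motif.width, revcomp=motif.revcomp, **params
            )
        except ValueError:
            continue
        if null.llr >= motif.llr:
            exceed += 1
    return (1 + exceed) / (n_shuffles + 1) * n_widths


def _mask_sites(strs: list[str], motif: DiscoveredMotif, min_prob: float = 0.5) -> int:
    masked = 0
    w = motif.width
    for site in motif.sites:
        if site.probability <= min_prob:
            continue
        s = strs[site.seq_index]
        strs[site.seq_index] = s[: site.offset] + "N" * w + s[site.offset + w :]
        masked += 1
    return masked


def discover_motifs(
    sequences,
    n_motifs: int = 30,
    max_width: int = 15,
    revcomp: bool = True,
    seed: int = 0,
    widths: tuple[int, ...] | None = None,
    n_starts: int = 50,
    start_iters: int = 1,
    max_iter: int = 200,
    tol: float = 1e-4,
    n_shuffles: int = 20,
    background: np.ndarray | None = None,
    min_sites: int = 2,
) -> list[DiscoveredMotif]:
    """Sequentially extract up to ``n_motifs`` motifs, best width per motif.

    For each motif every width on the candidate grid is fitted and the
    winner is the lowest Monte-Carlo E-value (ties: higher likelihood
    ratio).  The winner's confident sites are hard-masked before the next
    round; extraction stops early when no width yields at least
    ``min_sites`` confident sites.  The returned list is sorted by E-value
    ascending.
    """
    if n_motifs < 0:
        raise ValueError("n_motifs must be >= 0")
    strs, gene_ids = _as_strings(sequences)
    named = list(zip(strs, gene_ids))
    grid = tuple(w for w in (widths or DEFAULT_WIDTH_GRID) if MIN_WIDTH <= w <= max_width)
    if not grid:
        raise ValueError("empty width grid")
    bg = sq.background_composition(strs) if background is None else np.asarray(background, float)

    work = list(strs)
    found: list[DiscoveredMotif] = []
    for idx in range(n_motifs):
        candidates: list[DiscoveredMotif] = []
        wrapped = [PromoterSequence(g, s) for s, g in zip(work, gene_ids)]
        for w in grid:
            try:
                m = em_zoops(
                    wrapped, w, background=bg, revcomp=revcomp,
                    max_iter=max_iter, tol=tol, seed=seed,
                    n_starts=n_starts, start_iters=start_iters,
                    motif_id=f"DENOVO{idx + 1}",
                )
            except ValueError:
                continue
            m.e_value = motif_e_value(
                m, work, n_shuffles=n_shuffles,
                seed=(seed * 1009 + idx * 131 + w) % (2**31), n_widths=len(grid),
            )
            candidates.append(m)
        if not candidates:
            logger.info("motif extraction stopped after %d motifs (no fit possible)", idx)
            break
        best = min(candidates, key=lambda m: (m.e_value, -m.llr, m.width))
        confident = sum(1 for s in best.sites if s.probability > 0.5)
        if confident < min_sites:
            logger.info(
                "motif extraction stopped after %d motifs (best candidate has %d confident sites)",
                idx, confident,
            )
            break
        found.append(best)
        _mask_sites(work, best)
    found.sort(key=lambda m: (m.e_value, -m.llr))
    return found
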