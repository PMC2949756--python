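"""Shared sequence numerics: encoding, window scoring, shuffling.

Sequences are encoded as small integer arrays (A=0, C=1, G=2, T=3, N=4) and
padded into a rectangular matrix so PWM window scores for a whole promoter
set can be computed with vectorized gathers.  Windows touching an N (masked
repeat or pad) score -inf and are excluded everywhere downstream.
"""

from __future__ import annotations

import re

import numpy as np

BASES = "ACGT"
N_CODE = 4
_LUT = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

#: complement permutation on codes (A<->T, C<->G, N->N)
COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_COMP_STR = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def encode_set(seqs: list[str]) -> np.ndarray:
    """Encode sequences into an (n, Lmax) matrix padded with N codes."""
    n = len(seqs)
    lmax = max((len(s) for s in seqs), default=0)
    codes = np.full((n, lmax), N_CODE, dtype=np.int8)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = encode(s)
    return codes


def background_composition(seqs: list[str], pseudocount: float = 1.0) -> np.ndarray:
    """0-order ACGT composition of a sequence set (N ignored)."""
    counts = np.full(4, pseudocount, dtype=float)
    for s in seqs:
        c = np.bincount(encode(s), minlength=5)[:4]
        counts += c
    return counts / counts.sum()


def window_scores(codes: np.ndarray, logp: np.ndarray, width: int) -> np.ndarray:
    """Sum of per-position scores over every window of ``width``.

    ``logp`` is (width, 5); column 4 (N) should be -inf so that windows
    containing N score -inf.  Returns an (n, L - width + 1) matrix.
    """
    n, L = codes.shape
    m = L - width + 1
    if m <= 0:
        return np.full((n, 0), -np.inf)
    scores = np.zeros((n, m))
    with np.errstate(invalid="ignore"):
        for k in range(width):
            scores += logp[k][codes[:, k : k + m]]
    return scores


def extend_logp(logp4: np.ndarray) -> np.ndarray:
    """Append an all -inf N column to a (width, 4) score matrix."""
    w = logp4.shape[0]
    out = np.full((w, 5), -np.inf)
    out[:, :4] = logp4
    return out


def bg_window_scores(codes: np.ndarray, log_bg: np.ndarray, width: int) -> np.ndarray:
    """Background log-probability of every window under a 0-order model.

    N positions contribute 0 to the running sum (their windows are excluded
    by the motif side anyway)."""
    n, L = codes.shape
    m = L - width + 1
    if m <= 0:
        return np.full((n, 0), 0.0)
    per_pos = np.concatenate([log_bg, [0.0]])[codes]
    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(per_pos, axis=1)], axis=1)
    return cs[:, width:] - cs[:, :-width]


def window_word_codes(codes: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer code of every window plus a validity mask (no N)."""
    n, L = codes.shape
    m = L - width + 1
    if m <= 0:
        return np.zeros((n, 0), dtype=np.int64), np.zeros((n, 0), dtype=bool)
    vals = np.zeros((n, m), dtype=np.int64)
    valid = np.ones((n, m), dtype=bool)
    for k in range(width):
        col = codes[:, k : k + m]
        valid &= col < N_CODE
        vals = vals * 4 + np.where(col < N_CODE, col, 0)
    return vals, valid


def word_from_code(code: int, width: int) -> str:
    letters = []
    for _ in range(width):
        letters.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(letters))


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul–Erickson)
# ---------------------------------------------------------------------------

def _shuffle_segment(s: str, rng: np.random.Generator) -> str:
    if len(s) <= 3:
        return s
    chars = sorted(set(s))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    # choose a designated final out-edge per vertex forming an arborescence
    # rooted at the terminal character; retry until connected
    last_edge: dict[str, str] = {}
    for _attempt in range(200):
        last_edge = {
            c: edges[c][int(rng.integers(len(edges[c])))] for c in chars if c != last
        }
        ok = True
        for c in chars:
            if c == last:
                continue
            cur, seen = c, set()
            while cur != last and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable on DNA alphabets
        return s

    out_lists: dict[str, list[str]] = {}
    for c in chars:
        rest = list(edges[c])
        if c != last:
            rest.remove(last_edge[c])
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        if c != last:
            rest.append(last_edge[c])
        out_lists[c] = rest

    result = [s[0]]
    ptr = {c: 0 for c in chars}
    cur = s[0]
    while ptr[cur] < len(out_lists[cur]):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Masked (N) runs stay in place; each unmasked segment is shuffled
    independently with the Altschul–Erickson Eulerian-path construction, so
    first-order structure is preserved within segments.
    """
    parts: list[str] = []
    for m in re.finditer(r"[ACGT]+|[^ACGT]+", seq.upper()):
        chunk = m.group(0)
        if chunk[0] in BASES:
            parts.append(_shuffle_segment(chunk, rng))
        else:
            parts.append(chunk)
    return "".join(parts)
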