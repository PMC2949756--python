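"""EM/ZOOPS motif discovery: oracles, invariants, planted recovery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lpsmotif.discovery import (
    NULL_REFIT_PARAMS,
    discover_motifs,
    em_zoops,
    motif_e_value,
)
from lpsmotif import seqs as sq


def planted_sequences(word, n=10, length=60, seed=0, strand="+"):
    rng = np.random.default_rng(seed)
    out, offsets = [], []
    w = len(word)
    ins = word if strand == "+" else sq.revcomp(word)
    for _ in range(n):
        bg = "".join(rng.choice(list("ACGT"), length))
        off = int(rng.integers(0, length - w + 1))
        out.append(bg[:off] + ins + bg[off + w:])
        offsets.append(off)
    return out, offsets


class TestEmZoops:
    def test_noiseless_plant_recovered_with_concentrated_posteriors(self):
        word = "ACGTTGCAA"
        seqs, offsets = planted_sequences(word, seed=0)
        m = em_zoops(seqs, len(word))
        assert m.consensus() in (word, sq.revcomp(word))
        hits = sum(1 for s in m.sites if s.offset == offsets[s.seq_index] and s.probability > 0.9)
        assert hits >= 9

    def test_single_iteration_matches_hand_computed_updates(self):
        # two length-6 sequences, width 4, forward strand only, uniform
        # background, hand-specified start; oracle enumerates all offsets
        seqs = ["ACGTAC", "TTACGT"]
        width, gamma0 = 4, 0.5
        bg = np.full(4, 0.25)
        init = np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.1, 0.1, 0.7, 0.1],
            [0.1, 0.1, 0.1, 0.7],
        ])
        pseudo = 1e-3

        # independent arithmetic: posterior per offset, then M-step
        idx = {b: i for i, b in enumerate("ACGT")}
        counts = np.zeros((width, 4))
        occ_sum, llr_sum = 0.0, 0.0
        posts_all = []
        for s in seqs:
            windows = [s[j:j + width] for j in range(len(s) - width + 1)]
            ratios = []
            for win in windows:
                pm = np.prod([init[k, idx[c]] for k, c in enumerate(win)])
                ratios.append(pm / 0.25 ** width)
            M = len(windows)
            Z = (1 - gamma0) + gamma0 / M * sum(ratios)
            posts = [gamma0 / M * r / Z for r in ratios]
            posts_all.append(posts)
            for win, p in zip(windows, posts):
                for k, c in enumerate(win):
                    counts[k, idx[c]] += p
            occ_sum += sum(posts)
            llr_sum += np.log(Z)
        counts += pseudo * bg
        expected_probs = counts / counts.sum(axis=1, keepdims=True)
        expected_gamma = occ_sum / len(seqs)

        m = em_zoops(seqs, width, background=bg, revcomp=False,
                     init_pwm=init, start_iters=1, max_iter=0, pseudocount=pseudo)
        assert np.allclose(m.pwm.probs, expected_probs, atol=1e-5)
        assert m.gamma == pytest.approx(expected_gamma, abs=1e-5)
        assert m.llr == pytest.approx(llr_sum, abs=1e-4)

    def test_likelihood_ascends_every_iteration(self):
        seqs, _ = planted_sequences("TGACGTCA", n=12, length=80, seed=3)
        m = em_zoops(seqs, 8)
        h = m.loglik_history
        assert len(h) >= 2
        assert all(b >= a - 1e-6 * (1 + abs(a)) for a, b in zip(h, h[1:]))

    def test_zoops_occurrence_posteriors_bounded_by_one(self):
        seqs, _ = planted_sequences("GGATCCAT", n=8, length=50, seed=4)
        m = em_zoops(seqs, 8)
        assert all(0.0 <= q <= 1.0 + 1e-9 for q in m.occurrence_posteriors)

    def test_masked_positions_never_chosen_as_sites(self):
        # only one admissible window per sequence; everything else is N
        word = "ACGTACGT"
        seqs = []
        for off in (3, 10):
            s = ["N"] * 30
            s[off:off + 8] = list(word)
            seqs.append("".join(s))
        m = em_zoops(seqs, 8, revcomp=False)
        assert [s.offset for s in sorted(m.sites, key=lambda x: x.seq_index)] == [3, 10]

    def test_strand_symmetry_under_input_reverse_complement(self):
        seqs, _ = planted_sequences("ACGGTTCA", n=10, length=60, seed=5)
        fwd = em_zoops(seqs, 8)
        rev = em_zoops([sq.revcomp(s) for s in seqs], 8)
        same = np.allclose(fwd.pwm.probs, rev.pwm.probs, atol=5e-2)
        flipped = np.allclose(fwd.pwm.probs, rev.pwm.reverse_complement().probs, atol=5e-2)
        assert same or flipped

    def test_width_and_input_validation(self):
        seqs, _ = planted_sequences("ACGTACGT", n=4)
        with pytest.raises(ValueError, match="width"):
            em_zoops(seqs, 3)
        with pytest.raises(ValueError):
            em_zoops(["ACG", "NNNNNNNN"], 6)


class TestDiscoverMotifs:
    def test_two_disjoint_plants_both_recovered(self):
        word_a, word_b = "ACGTTGCA", "TTGGCCAA"
        successes = 0
        for seed in range(10):
            sa, _ = planted_sequences(word_a, n=7, length=70, seed=seed * 2 + 1)
            sb, _ = planted_sequences(word_b, n=7, length=70, seed=seed * 2 + 2)
            motifs = discover_motifs(
                sa + sb, n_motifs=2, widths=(8,), n_starts=20,
                n_shuffles=3, seed=seed, tol=1e-3,
            )
            found = [m.consensus() for m in motifs]

            def matches(word):
                rc = sq.revcomp(word)
                return any(
                    min(sum(a != b for a, b in zip(c, word)),
                        sum(a != b for a, b in zip(c, rc))) <= 1
                    for c in found
                )
            successes += matches(word_a) and matches(word_b)
        assert successes >= 9

    def test_zero_motifs_requested_gives_empty_list(self):
        seqs, _ = planted_sequences("ACGTACGT", n=4)
        assert discover_motifs(seqs, n_motifs=0) == []

    def test_reverse_strand_plant_recovered_with_revcomp(self):
        word = "ACGTTGCAA"
        seqs, _ = planted_sequences(word, n=10, length=60, seed=7, strand="-")
        motifs = discover_motifs(seqs, n_motifs=1, widths=(9,), n_starts=20,
                                 n_shuffles=3, seed=7)
        assert motifs
        c = motifs[0].consensus()
        assert min(sum(a != b for a, b in zip(c, word)),
                   sum(a != b for a, b in zip(c, sq.revcomp(word)))) <= 1


class TestEValue:
    def test_strong_plant_sits_at_monte_carlo_floor(self):
        seqs, _ = planted_sequences("ACGTTGCAA", n=10, length=60, seed=0)
        m = em_zoops(seqs, 9)
        e = motif_e_value(m, seqs, n_shuffles=9, seed=1, n_widths=3)
        assert e == pytest.approx(3 / 10)

    def test_same_seed_same_value(self):
        seqs, _ = planted_sequences("ACGTTGCAA", n=6, length=40, seed=2)
        m = em_zoops(seqs, 9)
        e1 = motif_e_value(m, seqs, n_shuffles=5, seed=42)
        e2 = motif_e_value(m, seqs, n_shuffles=5, seed=42)
        assert e1 == e2
        with pytest.raises(ValueError):
            motif_e_value(m, seqs, n_shuffles=0, seed=1)

    def test_null_fit_e_values_roughly_uniform(self):
        # fit on shuffled (null) data with the same cheap config used for
        # the null refits, so observed and null statistics are exchangeable
        rng = np.random.default_rng(123)
        es = []
        for trial in range(20):
            seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(6)]
            m = em_zoops(seqs, 6, **NULL_REFIT_PARAMS)
            es.append(motif_e_value(m, seqs, n_shuffles=9, seed=trial))
        bins = [sum(1 for e in es if e <= 0.3),
                sum(1 for e in es if 0.3 < e <= 0.7),
                sum(1 for e in es if e > 0.7)]
        # thirds of the attainable range; chi-square sanity at the 1% level
        p = stats.chisquare(bins, f_exp=[20 * 0.3, 20 * 0.4, 20 * 0.3]).pvalue
        assert p > 0.01


class TestDinucleotideShuffle:
    @pytest.mark.parametrize("seed", range(3))
    def test_preserves_dinucleotide_counts_and_masked_runs(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq = seq[:50] + "NNNNN" + seq[55:]
        out = sq.dinucleotide_shuffle(seq, np.random.default_rng(seed + 10))
        assert len(out) == len(seq)
        assert [i for i, c in enumerate(out) if c == "N"] == \
               [i for i, c in enumerate(seq) if c == "N"]

        def dinucs(s):
            counts = {}
            for seg in s.split("N"):
                for a, b in zip(seg, seg[1:]):
                    counts[a + b] = counts.get(a + b, 0) + 1
            return counts
        assert dinucs(out) == dinucs(seq)

    def test_shuffle_actually_permutes(self):
        seq = "ACGTACGTACGTACGTACGTGGCCAATTGGCCAATT" * 3
        out = sq.dinucleotide_shuffle(seq, np.random.default_rng(0))
        assert out != seq
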