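"""Motif-expression linear model: counting, least squares, TCS ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpsmotif.io import PWM, PromoterSequence
from lpsmotif.tcs import (
    MotifCountMatrix,
    build_count_matrix,
    count_motif_occurrences,
    count_word_occurrences,
    fit_linear_model,
    random_response,
    run_tcs,
    word_universe,
)


class TestWordCounting:
    def test_overlapping_forward_occurrences(self):
        assert count_word_occurrences("ACGT", "TACGTACGTT", both_strands=False) == 2

    def test_palindromic_word_counts_once_per_strand(self):
        # revcomp(GGCC) == GGCC, so one physical site counts on both strands
        assert count_word_occurrences("GGCC", "GGCCAA", both_strands=True) == 2

    def test_brute_force_both_strand_scan(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300))
        word = "ACGT"
        comp = str.maketrans("ACGT", "TGCA")
        rc = word.translate(comp)[::-1]

        def brute(w):
            return sum(1 for i in range(len(seq) - 3) if seq[i:i + 4] == w)

        assert count_word_occurrences(word, seq) == brute(word) + brute(rc)

    def test_n_never_matches_and_long_word_warns(self):
        assert count_word_occurrences("ACGT", "N" * 50) == 0
        assert count_word_occurrences("ACGTACGT", "ACG") == 0

    def test_word_alphabet_validated(self):
        with pytest.raises(ValueError):
            count_word_occurrences("ACGU", "ACGT")


class TestPwmCounting:
    @staticmethod
    def sharp_pwm(word):
        idx = {b: i for i, b in enumerate("ACGT")}
        probs = np.full((len(word), 4), 0.01)
        for k, c in enumerate(word):
            probs[k, idx[c]] = 0.97
        return PWM("M1", "X", probs)

    def test_consensus_site_detected_in_background(self):
        pwm = self.sharp_pwm("ACGTTGCAAT")
        seq = "T" * 40 + "ACGTTGCAAT" + "T" * 40
        bg = np.full(4, 0.25)
        assert count_motif_occurrences(pwm, seq, background=bg) >= 1
        assert count_motif_occurrences(pwm, "N" * 90, background=bg) == 0

    def test_threshold_scales_with_rel_parameter(self):
        pwm = self.sharp_pwm("ACGTTGCAAT")
        near_miss = "T" * 40 + "ACGTTGCAAA" + "T" * 40  # one mismatch
        bg = np.full(4, 0.25)
        strict = count_motif_occurrences(pwm, near_miss, background=bg, rel_threshold=0.95)
        loose = count_motif_occurrences(pwm, near_miss, background=bg, rel_threshold=0.5)
        assert strict == 0 and loose >= 1


class TestLinearModel:
    def test_exact_line_recovered(self):
        fit = fit_linear_model(np.array([[0.], [1.], [2.]]), [1, 3, 5])
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-20)

    def test_two_motif_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, size=(6, 2)).astype(float)
        while np.linalg.matrix_rank(np.column_stack([np.ones(6), X])) < 3:
            X = rng.integers(0, 5, size=(6, 2)).astype(float)
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        fit = fit_linear_model(X, y)
        assert np.allclose(fit.coefficients, [2.0, -1.0], atol=1e-8)
        # independent solve of the normal equations
        Xa = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        assert np.allclose(fit.coefficients, beta[1:], atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_well_conditioned_designs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 10, 5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = fit_linear_model(X, y)
        Xa = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        assert np.allclose(fit.coefficients, beta[1:], atol=1e-8)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_constant_column_confounded_with_intercept(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        fit = fit_linear_model(X, np.arange(5.0) * 3 + 1)
        assert fit.confounded == [0]
        assert fit.coefficients[0] == 0.0
        assert fit.coefficients[1] == pytest.approx(3.0)

    def test_underdetermined_design_uses_ridge(self):
        X = np.random.default_rng(0).normal(size=(3, 4))
        fit = fit_linear_model(X, [1.0, 2.0, 3.0])
        assert fit.used_ridge


def driver_promoters(seed, n=30, length=150, word="ACGTTGCA"):
    """Promoters with 0-3 planted copies of a driver word; response 3*count."""
    rng = np.random.default_rng(seed)
    promoters, response = [], []
    for i in range(n):
        s = list("".join(rng.choice(list("ACGT"), length)))
        copies = int(rng.integers(0, 4))
        for c in range(copies):
            off = 10 + c * 30
            s[off:off + len(word)] = list(word)
        seq = "".join(s)
        promoters.append(PromoterSequence(f"g{i:02d}", seq))
        response.append(3.0 * count_word_occurrences(word, seq))
    return promoters, np.array(response)


DECOY_WORDS = ["TTAACGGC", "CCGGATTA", "AATTCCGG", "GGCCTTAA", "ACACGTGT",
               "TGTGCACA", "CAGTACTG", "GTCATGAC", "TCCGGAAT"]


class TestRunTcs:
    def test_noiseless_driver_ranks_first_across_seeds(self):
        word = "ACGTTGCA"
        wins = 0
        for seed in range(10):
            promoters, y = driver_promoters(seed)
            results = run_tcs(promoters, y, motif_universe=[word] + DECOY_WORDS,
                              subset_size=4, n_iterations=150, seed=seed)
            wins += results[0].motif_id == word
        assert wins >= 9

    def test_shuffled_response_degrades_driver_score(self):
        word = "ACGTTGCA"
        wins = 0
        for seed in range(10):
            promoters, y = driver_promoters(seed)
            rng = np.random.default_rng(seed + 500)
            y_perm = rng.permutation(y)
            kw = dict(motif_universe=[word] + DECOY_WORDS, subset_size=4,
                      n_iterations=150, seed=seed)
            true_tcs = next(r.tcs for r in run_tcs(promoters, y, **kw) if r.motif_id == word)
            perm_tcs = next(r.tcs for r in run_tcs(promoters, y_perm, **kw) if r.motif_id == word)
            wins += perm_tcs < true_tcs
        assert wins >= 9

    def test_single_iteration_whole_universe_reduces_to_one_fit(self):
        promoters, y = driver_promoters(3)
        universe = ["ACGTTGCA"] + DECOY_WORDS
        counts = build_count_matrix(promoters, universe)
        results = run_tcs(promoters, y, motif_universe=universe,
                          subset_size=len(universe), n_iterations=1, seed=0)
        fit = fit_linear_model(counts, y)
        std = counts.counts.astype(float).std(axis=0)
        expected = np.abs(fit.coefficients) * std / y.std()
        by_id = {m: e for m, e in zip(counts.motifs, expected)}
        for r in results:
            assert r.tcs == pytest.approx(by_id[r.motif_id], abs=1e-12)
            assert r.times_sampled == 1

    def test_response_scaling_leaves_standardized_tcs_invariant(self):
        promoters, y = driver_promoters(5)
        kw = dict(motif_universe=["ACGTTGCA"] + DECOY_WORDS, subset_size=4,
                  n_iterations=50, seed=2)
        a = run_tcs(promoters, y, **kw)
        b = run_tcs(promoters, 7.5 * y, **kw)
        for ra, rb in zip(a, b):
            assert ra.motif_id == rb.motif_id
            assert ra.tcs == pytest.approx(rb.tcs, rel=1e-9)
            assert rb.mean_coefficient == pytest.approx(7.5 * ra.mean_coefficient, rel=1e-9)

    def test_parameter_validation(self):
        promoters, y = driver_promoters(0, n=5)
        with pytest.raises(ValueError, match="subset_size"):
            run_tcs(promoters, y, motif_universe=["ACGT"], subset_size=2, n_iterations=1)
        with pytest.raises(ValueError, match="n_iterations"):
            run_tcs(promoters, y, motif_universe=["ACGT", "GGCC"],
                    subset_size=1, n_iterations=0)


class TestWordUniverse:
    def test_pruning_threshold_respected(self):
        word = "ACGTTGCA"
        promoters = [PromoterSequence(f"g{i}", "T" * 20 + word + "T" * 20) for i in range(3)]
        universe = word_universe(promoters, k=8, min_count=3)
        assert word in universe
        assert "ACACACAC" not in universe

    def test_counts_include_reverse_strand(self):
        # the word appears once forward; its reverse complement twice
        word, rc = "AACCGGTT", "AACCGGTT"  # palindromic: every hit counts twice
        promoters = [PromoterSequence("g", "TTTTT" + word + "TTTTT")]
        counts = build_count_matrix(promoters, [word])
        assert counts.counts[0, 0] == 2


class TestRandomResponse:
    @settings(max_examples=25, deadline=None)
    @given(lo=st.floats(-5, 5), width=st.floats(0, 10), n=st.integers(0, 200),
           seed=st.integers(0, 2**31 - 1))
    def test_bounds_and_determinism(self, lo, width, n, seed):
        hi = lo + width
        draws = random_response(lo, hi, n, seed=seed)
        assert len(draws) == n
        assert np.all(draws >= lo) and np.all(draws <= hi)
        assert np.array_equal(draws, random_response(lo, hi, n, seed=seed))

    def test_degenerate_and_invalid_ranges(self):
        assert np.all(random_response(2.0, 2.0, 5, seed=1) == 2.0)
        with pytest.raises(ValueError):
            random_response(1.0, 0.0, 3)
        with pytest.raises(ValueError):
            random_response(0.0, 1.0, -1)


def test_count_matrix_dimension_validation():
    with pytest.raises(ValueError):
        MotifCountMatrix(["g1"], ["m1", "m2"], np.zeros((1, 1)))
    with pytest.raises(ValueError):
        MotifCountMatrix(["g1"], ["m1"], np.array([[-1]]))
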