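"""Phenotype classification: ratio filters, Welch test, signatures, nulls."""

import math

import numpy as np
import pytest
from scipy import stats

from lpsmotif.classify import (
    ANTI,
    PRO,
    UNCLASSIFIED,
    classify_gene,
    classify_matrix,
    condition_averages,
    cross_dataset_pattern,
    random_gene_pattern_null,
    relative_profiles,
    twofold_signature,
    welch_t_test,
)
from lpsmotif.io import ExpressionMatrix
from conftest import make_matrix, make_record


def welch_oracle(a, b):
    """Independent Welch p-value: explicit statistic + t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestConditionAverages:
    def test_arithmetic_means(self):
        rec = make_record("p", "g", (100, 110), (400, 420), (150, 160))
        assert condition_averages(rec) == pytest.approx((105, 410, 155))

    def test_single_replicate_is_identity(self):
        rec = make_record("p", "g", (7,), (9,), (11,))
        assert condition_averages(rec) == pytest.approx((7, 9, 11))

    def test_all_zero_record_is_unclassified_downstream(self):
        rec = make_record("p", "g", (0, 0), (0, 0), (0, 0))
        assert condition_averages(rec) == (0, 0, 0)
        call = classify_gene(rec)
        assert call.label == UNCLASSIFIED
        assert "zero denominator" in call.reason

    def test_missing_condition_raises(self):
        rec = make_record("p", "g", (1, 1), (1, 1), (1, 1))
        del rec.values["TL"]
        with pytest.raises(KeyError):
            condition_averages(rec)


class TestWelch:
    def test_printed_toy_groups_match_closed_form(self):
        # t = -5/sqrt(2) at Welch df = 2; closed-form t CDF for df=2 is
        # 1/2 + t / (2*sqrt(2)*sqrt(1 + t^2/2))
        t = 5 / math.sqrt(2)
        p_closed = 2 * (1 - (0.5 + t / (2 * math.sqrt(2) * math.sqrt(1 + t * t / 2))))
        assert p_closed == pytest.approx(0.0715, abs=5e-4)
        assert welch_t_test([1, 3], [6, 8]) == pytest.approx(p_closed, rel=1e-9)

    def test_identical_groups_give_p_one(self):
        assert welch_t_test([5, 9], [5, 9]) == 1.0

    def test_zero_variance_conventions(self):
        assert welch_t_test([2, 2], [3, 3]) == 0.0
        assert welch_t_test([4, 4], [4, 4]) == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1], [2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.gamma(5, 10, size=rng.integers(2, 6))
        b = rng.gamma(5, 12, size=rng.integers(2, 6))
        assert welch_t_test(a, b) == pytest.approx(welch_oracle(a, b), rel=1e-10)


class TestClassifyGene:
    def test_induced_then_repressed_is_pro_inflammatory(self):
        rec = make_record("p", "g", (100, 110), (400, 420), (150, 160))
        call = classify_gene(rec)
        assert welch_oracle(rec.values["N"], rec.values["TL"]) < 0.05
        assert call.label == PRO
        assert call.r1 > 1 and call.r2 < 1

    def test_flat_record_fails_strict_ratio(self):
        rec = make_record("p", "g", (50, 50), (50, 50), (50, 50))
        assert classify_gene(rec).label == UNCLASSIFIED

    def test_escalating_record_is_antibacterial(self):
        rec = make_record("p", "g", (10, 12), (30, 32), (90, 95))
        call = classify_gene(rec)
        assert welch_oracle(rec.values["N"], rec.values["TL"]) < 0.05
        assert call.r1 == pytest.approx(31 / 11)
        assert call.r2 == pytest.approx(92.5 / 31)
        assert call.label == ANTI

    def test_alpha_validated(self):
        rec = make_record("p", "g", (1, 2), (3, 4), (5, 6))
        with pytest.raises(ValueError):
            classify_gene(rec, alpha=1.5)

    def test_optional_contrast_uses_nl_group(self):
        # NL differs from N strongly but TL is indistinguishable from N
        rec = make_record("p", "g", (100, 101), (400, 401), (100.5, 101.5))
        assert classify_gene(rec, contrast="N_vs_TL").label == UNCLASSIFIED
        assert classify_gene(rec, contrast="N_vs_NL").label == PRO


def brute_force_classify(matrix: ExpressionMatrix, alpha=0.05):
    """Independent per-record re-derivation of the filtering rules."""
    labels = {}
    for rec in matrix:
        n, nl, tl = (rec.values[c].mean() for c in ("N", "NL", "TL"))
        if n == 0 or nl == 0:
            labels[rec.probe_id] = UNCLASSIFIED
            continue
        a, b = rec.values["N"], rec.values["TL"]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = welch_oracle(a, b)
        if nl / n > 1 and p < alpha and tl / nl < 1:
            labels[rec.probe_id] = PRO
        elif nl / n > 1 and p < alpha and tl / nl > 1:
            labels[rec.probe_id] = ANTI
        else:
            labels[rec.probe_id] = UNCLASSIFIED
    return labels


def random_small_matrix(rng, n_records):
    rows = []
    for i in range(n_records):
        base = rng.uniform(0, 50)
        rows.append((
            f"p{i}", f"g{i % max(1, n_records - 2)}",
            np.round(base * rng.uniform(0, 2, 2), 3),
            np.round(base * rng.uniform(0, 4, 2), 3),
            np.round(base * rng.uniform(0, 4, 2), 3),
        ))
    return make_matrix(rows)


class TestClassifyMatrix:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_small_matrix(rng, int(rng.integers(5, 50)))
        result = classify_matrix(matrix)
        expected = brute_force_classify(matrix)
        got = {c.probe_id: c.label for c in result.calls}
        assert got == expected

    def test_every_probe_gets_exactly_one_label_and_sets_disjoint(self):
        rng = np.random.default_rng(99)
        matrix = random_small_matrix(rng, 40)
        result = classify_matrix(matrix)
        assert len(result.calls) == len(matrix)
        assert not set(result.pro_probe_ids) & set(result.anti_probe_ids)

    @pytest.mark.parametrize("seed", range(4))
    def test_raising_alpha_never_shrinks_classified_sets(self, seed):
        rng = np.random.default_rng(seed + 100)
        matrix = random_small_matrix(rng, 40)
        lo = classify_matrix(matrix, alpha=0.01)
        hi = classify_matrix(matrix, alpha=0.2)
        assert set(lo.pro_probe_ids) <= set(hi.pro_probe_ids)
        assert set(lo.anti_probe_ids) <= set(hi.anti_probe_ids)

    def test_empty_matrix_not_constructible_but_no_hits_gives_empty_lists(self):
        matrix = make_matrix([("p1", "g1", (5, 5), (5, 5), (5, 5))])
        result = classify_matrix(matrix)
        assert result.pro_genes == [] and result.anti_genes == []


class TestTwofoldSignature:
    def test_exact_twofold_boundary_included(self):
        matrix = make_matrix([
            ("p1", "in", (10, 10), (20, 20), (10, 10)),
            ("p2", "out", (10, 10), (15, 15), (10, 10)),
        ])
        sig = twofold_signature(matrix)
        assert sig.genes == ["in"]

    def test_zero_denominator_excluded(self):
        matrix = make_matrix([("p1", "g", (0, 0), (20, 20), (10, 10))])
        assert twofold_signature(matrix).genes == []


class TestRelativeProfiles:
    def test_scaling_against_global_n_maximum(self):
        matrix = make_matrix([
            ("p1", "big", (5000, 5000), (6000, 6000), (100, 100)),
            ("p2", "g", (500, 500), (2000, 2000), (600, 600)),
        ])
        profiles = {p.gene_symbol: p for p in relative_profiles(matrix, ["g", "big"])}
        assert profiles["g"].rel_n == pytest.approx(0.1)
        assert profiles["g"].rel_nl == pytest.approx(0.4)
        assert profiles["g"].rel_tl == pytest.approx(0.12)
        assert profiles["big"].rel_n == pytest.approx(1.0)

    def test_empty_gene_list_and_missing_gene(self):
        matrix = make_matrix([("p1", "g", (10, 10), (10, 10), (10, 10))])
        assert relative_profiles(matrix, []) == []
        assert relative_profiles(matrix, ["absent"]) == []


class TestCrossDataset:
    def test_repression_relative_to_induction_flags(self):
        matrix = make_matrix([
            ("p1", "tol", (10, 10), (40, 40), (10, 10), (10, 10)),   # TL/T=1 < NL/N=4
            ("p2", "same", (10, 10), (40, 40), (40, 40), (10, 10)),  # TL/T=4 == NL/N
        ])
        flags, count = cross_dataset_pattern(matrix, ["tol", "same"])
        assert flags == {"tol": True, "same": False}
        assert count == 1

    def test_requires_four_conditions(self):
        matrix = make_matrix([("p1", "g", (1, 1), (2, 2), (1, 1))])
        with pytest.raises(ValueError, match="T"):
            cross_dataset_pattern(matrix, ["g"])


class TestRandomGeneNull:
    @staticmethod
    def _matrix_with_pattern_fraction(n=200, positive=10):
        rows = []
        for i in range(n):
            if i < positive:
                rows.append((f"p{i}", f"g{i}", (10, 10), (40, 40), (10, 10)))
            else:
                rows.append((f"p{i}", f"g{i}", (10, 10), (11, 11), (10, 10)))
        return make_matrix(rows)

    def test_counts_near_binomial_expectation(self):
        # 5% pattern-positive genes, sets of 18: expectation 0.9 per set
        matrix = self._matrix_with_pattern_fraction()
        counts = random_gene_pattern_null(matrix, set_size=18, n_sets=10, seed=5)
        assert len(counts) == 10
        assert 0.0 <= np.mean(counts) <= 2.5
        assert max(counts) <= 5

    def test_seeded_determinism_and_degenerate_sizes(self):
        matrix = self._matrix_with_pattern_fraction(50, 5)
        a = random_gene_pattern_null(matrix, set_size=10, n_sets=5, seed=3)
        b = random_gene_pattern_null(matrix, set_size=10, n_sets=5, seed=3)
        assert a == b
        assert random_gene_pattern_null(matrix, set_size=0, n_sets=3, seed=1) == [0, 0, 0]
        with pytest.raises(ValueError):
            random_gene_pattern_null(matrix, set_size=51, n_sets=1, seed=1)


class TestBenjaminiHochbergOption:
    def test_off_by_default_and_never_adds_calls(self):
        rng = np.random.default_rng(42)
        matrix = random_small_matrix(rng, 40)
        plain = classify_matrix(matrix)
        adjusted = classify_matrix(matrix, p_adjust="bh")
        assert set(adjusted.pro_probe_ids) <= set(plain.pro_probe_ids)
        assert set(adjusted.anti_probe_ids) <= set(plain.anti_probe_ids)
        with pytest.raises(ValueError):
            classify_matrix(matrix, p_adjust="bonferroni")
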