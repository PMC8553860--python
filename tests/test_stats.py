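"""Validation statistics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cariescan.errors import ConfigurationError, DegenerateLabelsError, DomainError
from cariescan.stats import (
    ContingencyTable,
    auc_delong,
    burderer_n,
    cluster_se,
    delong_paired_test,
    letter_groups,
    mcnemar,
    mcnemar_bowker,
    mcnemar_bowker_table,
    mcnemar_counts,
    se_sp_acc,
    spearman_rs,
)


def brute_force_auc(scores, labels):
    """Pairwise win counting with ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


class TestAucDelong:
    def test_separable_scores_give_unit_auc(self):
        assert auc_delong([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).az == 1.0

    def test_all_ties_give_half(self):
        assert auc_delong([0.3] * 6, [1, 0, 1, 0, 1, 0]).az == 0.5

    def test_crossed_pairs_example(self):
        # two wins and two losses of the four positive/negative pairs
        res = auc_delong([0.8, 0.2, 0.1, 0.9], [False, False, True, True])
        assert res.az == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc_delong(scores, labels).az == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.ones(40, bool), np.zeros(78, bool)]
        scores = labels * 0.8 + rng.normal(0, 1, 118)
        se = auc_delong(scores, labels).az_se
        boots = np.empty(10_000)
        for i in range(10_000):
            idx = rng.integers(0, 118, 118)
            lab = labels[idx]
            if lab.all() or not lab.any():
                boots[i] = np.nan
                continue
            boots[i] = brute_force_auc(scores[idx], lab)
        boot_se = np.nanstd(boots, ddof=1)
        assert abs(se - boot_se) / boot_se < 0.15

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc_delong([0.1, 0.2], [True, True])


class TestDelongPairedTest:
    def test_self_comparison_is_null(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.9, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        assert delong_paired_test(scores, scores, labels) == (0.0, 1.0)

    def test_detects_a_separable_method_against_noise(self):
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(200):
            labels = np.r_[np.ones(60, bool), np.zeros(60, bool)]
            a = labels + rng.normal(0, 0.05, 120)   # nearly separable
            b = rng.normal(0, 1, 120)               # uninformative
            _, p = delong_paired_test(a, b, labels)
            wins += p < 0.05
        assert wins / 200 > 0.95

    def test_complete_case_pairing_drops_missing_sites(self):
        labels = [0, 0, 0, 1, 1, 1, 0, 1]
        a = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9, np.nan, 0.6]
        b = [0.2, 0.1, 0.4, 0.6, 0.9, 0.8, 0.5, np.nan]
        z, p = delong_paired_test(a, b, labels)
        assert 0 <= p <= 1


class TestProportions:
    def test_se_sp_acc_arithmetic(self):
        table = ContingencyTable(tp=9, fp=4, fn=1, tn=6)
        assert se_sp_acc(table) == (0.9, 0.6, 0.75)
        perfect = ContingencyTable(tp=5, fp=0, fn=0, tn=5)
        assert se_sp_acc(perfect) == (1.0, 1.0, 1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(DomainError):
            se_sp_acc(ContingencyTable(tp=0, fp=2, fn=0, tn=3))

    def test_per_cluster_counts_must_sum(self):
        with pytest.raises(DomainError):
            ContingencyTable(tp=2, fp=0, fn=0, tn=0,
                             per_cluster=[("T1", 1, 0, 0, 0)])

    def test_cluster_se_singleton_reduces_to_scaled_binomial(self):
        outcomes = np.r_[np.ones(50), np.zeros(50)]
        clusters = np.arange(100)
        expected = math.sqrt(0.25 / 100) * math.sqrt(100 / 99)
        assert cluster_se(outcomes, clusters) == pytest.approx(expected)

    def test_unanimous_clusters_inflate_the_naive_se(self):
        # 10 clusters of 4, half all-positive: between-cluster variance maximal
        outcomes = np.r_[np.ones(20), np.zeros(20)]
        clusters = np.repeat(np.arange(10), 4)
        naive = math.sqrt(0.25 / 40)
        assert cluster_se(outcomes, clusters) > naive

    def test_single_cluster_rejected(self):
        with pytest.raises(DomainError):
            cluster_se([1, 0, 1], ["T1", "T1", "T1"])


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        assert mcnemar_counts(7, 7) == 1.0

    def test_exact_binomial_example(self):
        # 12 discordant pairs split 10/2: two-sided exact binomial
        assert mcnemar_counts(10, 2) == pytest.approx(0.038574, abs=1e-5)

    def test_no_discordance_is_uninformative(self):
        assert mcnemar_counts(0, 0) == 1.0
        assert mcnemar([1, 1, 0], [1, 1, 0]) == 1.0


class TestMcNemarBowker:
    def test_symmetric_table_is_null(self):
        table = np.array([[5, 2, 1], [2, 7, 3], [1, 3, 9]])
        stat, df, p = mcnemar_bowker_table(table)
        assert stat == 0.0 and p == 1.0

    def test_single_asymmetric_pair(self):
        table = np.zeros((3, 3), int)
        table[0, 1], table[1, 0] = 5, 1
        stat, df, p = mcnemar_bowker_table(table)
        assert stat == pytest.approx(16 / 6)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(16 / 6, 1))

    def test_matches_statsmodels_on_full_tables(self):
        from statsmodels.stats.contingency_tables import SquareTable

        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(1, 20, size=(4, 4))
            stat, df, p = mcnemar_bowker_table(table)
            ref = SquareTable(table).symmetry(method="bowker")
            assert stat == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue))

    def test_paired_scores_interface(self):
        a = [0, 1, 2, 2, 1, 0, 2]
        b = [0, 1, 2, 1, 1, 0, 2]
        stat, df, p = mcnemar_bowker(a, b, 3)
        assert df == 1 and stat == pytest.approx(1.0)

    def test_non_square_rejected(self):
        with pytest.raises(ConfigurationError):
            mcnemar_bowker_table(np.zeros((2, 3)))


class TestSpearman:
    def test_monotone_and_reversed(self):
        clusters = ["a", "a", "b", "b", "c"]
        rs, _ = spearman_rs([1, 2, 3, 4, 5], [2, 4, 5, 7, 9], clusters, n_boot=10)
        assert rs == pytest.approx(1.0)
        rs, _ = spearman_rs([1, 2, 3, 4, 5], [9, 7, 5, 4, 2], clusters, n_boot=10)
        assert rs == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        a = np.array([1, 2, 2, 3, 5])
        b = np.array([2, 1, 2, 4, 4])
        oracle = np.corrcoef(sps.rankdata(a), sps.rankdata(b))[0, 1]
        rs, _ = spearman_rs(a, b, list("aabbc"), n_boot=10)
        assert rs == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            spearman_rs([1, 1, 1], [1, 2, 3], ["a", "b", "c"], n_boot=10)

    def test_bootstrap_se_is_seeded_and_positive(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, 60)
        b = a + rng.integers(0, 3, 60)
        clusters = np.repeat(np.arange(20), 3)
        r1 = spearman_rs(a, b, clusters, n_boot=200, rng=np.random.default_rng(7))
        r2 = spearman_rs(a, b, clusters, n_boot=200, rng=np.random.default_rng(7))
        assert r1 == r2
        assert r1[1] > 0


class TestLetterGroups:
    def test_no_differences_share_a_letter(self):
        p = np.ones((3, 3))
        assert letter_groups([0.9, 0.8, 0.7], p) == ["A", "A", "A"]

    def test_lowest_method_split_off(self):
        p = np.ones((3, 3))
        p[0, 2] = p[2, 0] = 0.01
        p[1, 2] = p[2, 1] = 0.01
        assert letter_groups([0.9, 0.8, 0.5], p) == ["A", "A", "B"]

    def test_all_different(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        assert letter_groups([0.7, 0.9, 0.8], p) == ["C", "A", "B"]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        est = np.array([0.91, 0.85, 0.7, 0.6])
        p = np.ones((4, 4))
        p[0, 3] = p[3, 0] = 0.01
        p[1, 3] = p[3, 1] = 0.04
        p[2, 3] = p[3, 2] = 0.2
        base = letter_groups(est, p)
        perm = rng.permutation(4)
        permuted = letter_groups(est[perm], p[np.ix_(perm, perm)])
        assert [permuted[list(perm).index(i)] for i in range(4)] == base


class TestBurderer:
    def test_study_inputs_without_prevalence_adjustment(self):
        # SE 0.84 / SP 0.76, 95% CI, absolute error 0.1
        assert burderer_n(0.84, 0.76, 0.05, 0.1, prevalence=1.0) == 71

    def test_study_inputs_at_even_prevalence(self):
        assert burderer_n(0.84, 0.76, 0.05, 0.1, prevalence=0.5) == 141

    def test_se_term_maximal_at_half(self):
        n_half = burderer_n(0.5, 0.0, 0.05, 0.1, prevalence=0.5)
        for se in (0.1, 0.3, 0.7, 0.9):
            assert burderer_n(se, 0.0, 0.05, 0.1, prevalence=0.5) <= n_half

    def test_invalid_prevalence_rejected(self):
        for prevalence in (0.0, -0.2, 1.3):
            with pytest.raises(DomainError):
                burderer_n(0.8, 0.8, prevalence=prevalence)
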