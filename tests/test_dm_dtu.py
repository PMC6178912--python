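import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from dtukit import dm_dtu
from dtukit.dm_dtu import (
    adjust_bh,
    chisq_lr_pvalue,
    dm_loglik,
    estimate_common_precision,
    fit_and_test_gene,
    sanitize_pvalues,
    transcript_test,
)

from conftest import make_dataset, sample_dm_counts


def dm_pmf_oracle(y, pi, gamma):
    """DM pmf via plain-float rising factorials (multinomial coeff included)."""

    def rising(x, m):
        out = 1.0
        for i in range(int(m)):
            out *= x + i
        return out

    n = int(sum(y))
    coeff = math.factorial(n)
    for yk in y:
        coeff //= math.factorial(int(yk))
    val = float(coeff) / rising(gamma, n)
    for yk, pk in zip(y, pi):
        val *= rising(gamma * pk, int(yk))
    return val


def multinomial_loglik(y, pi):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    pi = np.asarray(pi, dtype=float)
    return float(np.sum(y * np.log(pi)))  # multinomial coefficient omitted


class TestDmLoglik:
    def test_single_category_is_zero(self):
        assert dm_loglik(np.array([[7.0]]), np.array([1.0]), 5.0) == pytest.approx(0.0)

    def test_pair_example_pmf_one_third(self):
        # y=(1,1), pi=(1/2,1/2), gamma=2 has pmf 1/3; the implementation
        # omits the multinomial coefficient ln 2
        ll = dm_loglik(np.array([[1.0, 1.0]]), np.array([0.5, 0.5]), 2.0)
        assert ll + np.log(2.0) == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)

    def test_matches_pmf_oracle_on_small_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            K = rng.integers(2, 5)
            y = rng.integers(0, 21, size=K)
            pi = rng.dirichlet(np.ones(K))
            gamma = float(rng.uniform(0.5, 50))
            ll = dm_loglik(y[None, :], pi, gamma)
            coeff = math.lgamma(y.sum() + 1) - sum(math.lgamma(v + 1) for v in y)
            assert ll + coeff == pytest.approx(np.log(dm_pmf_oracle(y, pi, gamma)), abs=1e-8)

    def test_multinomial_limit(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 30, size=(4, 3)).astype(float)
        pi = np.array([0.5, 0.3, 0.2])
        assert dm_loglik(y, pi, 1e8) == pytest.approx(multinomial_loglik(y, pi), abs=1e-4)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            dm_loglik(np.array([[1.0, 1.0]]), np.array([0.5, 0.5]), 0.0)


class TestGeneFit:
    def test_five_transcript_two_group_df(self):
        rng = np.random.default_rng(13)
        counts = rng.integers(5, 100, size=(5, 12)).astype(float)
        fit = fit_and_test_gene(counts, np.array([1] * 6 + [2] * 6))
        assert fit.df == 4
        assert fit.lr >= 0

    def test_identical_groups_give_null_result(self):
        block = np.array([[30.0, 40.0, 50.0], [70.0, 60.0, 50.0]])
        counts = np.hstack([block, block])
        fit = fit_and_test_gene(counts, np.array([1, 1, 1, 2, 2, 2]))
        assert fit.lr == pytest.approx(0.0, abs=1e-4)
        assert np.isnan(fit.pvalue) or fit.pvalue > 0.99

    def test_complete_switch_is_overwhelming(self):
        counts = np.array([[1000.0] * 6 + [0.0] * 6, [0.0] * 6 + [1000.0] * 6])
        cond = np.array([1] * 6 + [2] * 6)
        fit = fit_and_test_gene(counts, cond)
        # complete switch: the likelihood is degenerate (one group all-zero
        # per transcript) so the p-value is flagged missing, but the LR is huge
        assert np.isnan(fit.pvalue)
        assert chisq_lr_pvalue(fit.lr, fit.df) < 1e-10

    def test_partial_switch_small_pvalue(self):
        counts = np.array([[900.0] * 6 + [100.0] * 6, [100.0] * 6 + [900.0] * 6])
        fit = fit_and_test_gene(counts, np.array([1] * 6 + [2] * 6))
        assert fit.pvalue < 1e-10

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(14)
        counts = rng.integers(0, 200, size=(3, 8)).astype(float)
        cond = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        a = fit_and_test_gene(counts, cond)
        b = fit_and_test_gene(counts, 3 - cond)
        assert a.lr == pytest.approx(b.lr, abs=1e-4)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(15)
        counts = rng.integers(1, 50, size=(4, 6)).astype(float)
        fit = fit_and_test_gene(counts, np.array([1, 1, 1, 2, 2, 2]))
        assert fit.pi_null.sum() == pytest.approx(1.0, abs=1e-9)
        for pi in fit.pi_by_group.values():
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_transcript_rejected(self):
        with pytest.raises(ValueError):
            fit_and_test_gene(np.array([[1.0, 2.0]]), np.array([1, 2]))


class TestTranscriptTest:
    def test_df_is_one_everywhere(self):
        rng = np.random.default_rng(16)
        counts = rng.integers(1, 80, size=(4, 8)).astype(float)
        res = transcript_test(counts, np.array([1] * 4 + [2] * 4), gamma=20.0)
        assert (res["df"] == 1).all()

    def test_two_transcript_gene_is_symmetric(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(1, 100, size=(2, 8)).astype(float)
        res = transcript_test(counts, np.array([1] * 4 + [2] * 4), gamma=15.0)
        assert res["lr"].iloc[0] == pytest.approx(res["lr"].iloc[1], abs=1e-6)
        assert res["pvalue"].iloc[0] == pytest.approx(res["pvalue"].iloc[1], abs=1e-9)

    def test_against_grid_search_beta_binomial_oracle(self):
        counts = np.array([[12.0, 3.0, 8.0, 2.0], [5.0, 9.0, 4.0, 11.0]])
        cond = np.array([1, 2, 1, 2])
        gamma = 10.0
        res = transcript_test(counts, cond, gamma=gamma)

        def best_ll(y2):
            grid = np.linspace(1e-4, 1 - 1e-4, 4001)
            lls = [dm_loglik(y2, np.array([p, 1 - p]), gamma) for p in grid]
            return max(lls)

        y_this = np.column_stack([counts[0], counts[1]])
        full = best_ll(y_this[cond == 1]) + best_ll(y_this[cond == 2])
        null = best_ll(y_this)
        assert res["lr"].iloc[0] == pytest.approx(2 * (full - null), abs=1e-3)


class TestPrecision:
    def test_recovers_simulated_precision(self):
        rng = np.random.default_rng(18)
        gene_ids, rows = [], []
        for g in range(50):
            K = 3
            pi = rng.dirichlet(np.ones(K) * 2)
            y = sample_dm_counts(rng, pi, 20.0, totals=np.full(24, 500))
            rows.append(y.T)
            gene_ids += [f"G{g}"] * K
        ds = make_dataset(gene_ids, np.vstack(rows), [1] * 12 + [2] * 12)
        est = estimate_common_precision(ds, subset_fraction=1.0, seed=0)
        assert 15 <= est <= 26

    def test_subset_fraction_one_is_deterministic(self):
        rng = np.random.default_rng(19)
        rowsets = [sample_dm_counts(rng, [0.6, 0.4], 10.0, np.full(8, 200)).T for _ in range(6)]
        ds = make_dataset(
            np.repeat([f"G{i}" for i in range(6)], 2), np.vstack(rowsets), [1] * 4 + [2] * 4
        )
        a = estimate_common_precision(ds, subset_fraction=1.0, seed=1)
        b = estimate_common_precision(ds, subset_fraction=1.0, seed=99)
        assert a == pytest.approx(b)

    def test_near_multinomial_hits_upper_bound(self):
        rng = np.random.default_rng(20)
        rowsets = [sample_dm_counts(rng, [0.5, 0.3, 0.2], 1e4, np.full(12, 800)).T for _ in range(10)]
        ds = make_dataset(
            np.repeat([f"G{i}" for i in range(10)], 3), np.vstack(rowsets), [1] * 6 + [2] * 6
        )
        est = estimate_common_precision(ds, subset_fraction=1.0, seed=2)
        assert est > 1e3  # pushed toward the upper optimization bound

    def test_per_gene_precision_recovery(self):
        # median relative error < 25% at 24 samples, totals 500, K=3
        rng = np.random.default_rng(21)
        errors = []
        for _ in range(100):
            pi = rng.dirichlet(np.ones(3) * 2)
            y = sample_dm_counts(rng, pi, 20.0, np.full(24, 500))
            fit = fit_and_test_gene(y.T, np.array([1] * 12 + [2] * 12))
            errors.append(abs(fit.gamma - 20.0) / 20.0)
        assert np.median(errors) < 0.25

    def test_empty_dataset_rejected(self):
        ds = make_dataset([], np.empty((0, 4)), [1, 1, 2, 2])
        with pytest.raises(ValueError):
            estimate_common_precision(ds, subset_fraction=1.0, seed=0)


class TestChisqPvalue:
    @pytest.mark.parametrize(
        "lr,df,expected",
        [
            (28.402587, 1, 9.853354e-08),
            (9.815460, 1, 1.730510e-03),
            (1.493561, 4, 8.277814e-01),
            (0.16587607, 1, 0.6838032),
        ],
    )
    def test_reference_rows(self, lr, df, expected):
        assert chisq_lr_pvalue(lr, df) == pytest.approx(expected, rel=1e-6)

    def test_zero_statistic(self):
        for df in (1, 2, 5):
            assert chisq_lr_pvalue(0.0, df) == 1.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            chisq_lr_pvalue(1.0, 0)


class TestPvalueUtilities:
    def test_sanitize_replaces_missing(self):
        np.testing.assert_allclose(
            sanitize_pvalues([0.2, np.nan, 0.9]), [0.2, 1.0, 0.9]
        )
        np.testing.assert_allclose(sanitize_pvalues([np.nan, np.nan]), [1.0, 1.0])
        np.testing.assert_allclose(sanitize_pvalues([0.1, 0.5]), [0.1, 0.5])

    def test_sanitize_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sanitize_pvalues([1.5])

    def test_bh_trivia(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_bh_never_below_raw(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(0, 1, 40)
        assert (adjust_bh(p) >= p - 1e-15).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_bh_matches_stepup_enumeration(self, pvals):
        p = np.array(pvals)
        got = adjust_bh(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expect = np.empty(m)
        # literal step-up: adj of i-th smallest is min over j >= i of p_(j)*m/j
        for rank, i in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            ]
            expect[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(23)
        p = rng.uniform(0, 1, 100)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjust_bh(p), ref, atol=1e-12)


class TestNullCalibration:
    def test_dm_pvalues_uniform_under_null(self):
        # shared proportions across groups: p-values roughly uniform
        rng = np.random.default_rng(24)
        pvals = []
        for _ in range(150):
            pi = rng.dirichlet(np.ones(3) * 2)
            y = sample_dm_counts(rng, pi, 20.0, np.full(12, 400))
            fit = fit_and_test_gene(y.T, np.array([1] * 6 + [2] * 6))
            if not np.isnan(fit.pvalue):
                pvals.append(fit.pvalue)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.12
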