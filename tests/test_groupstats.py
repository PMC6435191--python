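"""Summary-statistic tests, rank statistics, partial correlation, MANOVA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ewaskit.groupstats import (
    GroupSummary,
    chi_square_2x2,
    mann_whitney_u,
    mann_whitney_z,
    manova_pillai,
    partial_correlation,
    pooled_t_from_summary,
    spearman_with_bh,
    welch_t_from_summary,
)


class TestSummaryT:
    def test_equal_means_zero(self):
        s = GroupSummary(5.0, 1.0, 10)
        assert pooled_t_from_summary(s, s).statistic == 0
        assert welch_t_from_summary(s, s).statistic == 0

    def test_welch_equals_pooled_at_equal_n(self):
        s1, s2 = GroupSummary(3.0, 1.5, 12), GroupSummary(4.2, 2.5, 12)
        assert welch_t_from_summary(s1, s2).statistic == pytest.approx(
            pooled_t_from_summary(s1, s2).statistic, abs=1e-12
        )

    def test_welch_df_bounded_by_pooled_df(self):
        s1, s2 = GroupSummary(3.0, 1.5, 12), GroupSummary(4.2, 4.5, 30)
        assert welch_t_from_summary(s1, s2).df <= s1.n + s2.n - 2

    def test_matches_scipy_on_raw_data(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        s1 = GroupSummary(x.mean(), x.std(ddof=1), 20)
        s2 = GroupSummary(y.mean(), y.std(ddof=1), 15)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert welch_t_from_summary(s1, s2).statistic == pytest.approx(ref.statistic)
        assert welch_t_from_summary(s1, s2).p_two_sided == pytest.approx(ref.pvalue)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, 1.0, 1)


class TestMannWhitney:
    def test_identical_samples_zero(self):
        res = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0

    def test_enumeration_oracle_n2_plus_2(self):
        # brute force: U over all rank arrangements of {1,2,3,4} into two pairs
        x, y = [1.0, 2.0], [3.0, 4.0]
        values = [1.0, 2.0, 3.0, 4.0]
        us = []
        for pos in combinations(range(4), 2):
            xs = [values[i] for i in pos]
            ys = [values[i] for i in range(4) if i not in pos]
            us.append(mann_whitney_u(xs, ys))
        mu, sd = np.mean(us), np.std(us, ddof=0)
        observed_u = mann_whitney_u(x, y)
        assert observed_u == 0
        expected_z = (observed_u - mu) / sd
        assert mann_whitney_z(x, y).statistic == pytest.approx(expected_z)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 1, size=10)
        assert mann_whitney_z(x, y).statistic == pytest.approx(
            -mann_whitney_z(y, x).statistic
        )

    def test_all_tied_flagged(self):
        res = mann_whitney_z([2, 2], [2, 2])
        assert res.statistic == 0 and res.flag == "all values tied"

    def test_sign_follows_location(self):
        assert mann_whitney_z([5, 6, 7], [1, 2, 3]).statistic > 0


class TestChiSquare:
    def test_direct_formula_on_gender_counts(self):
        # 9/20 females/males vs 11/18: direct Pearson value, no correction
        res = chi_square_2x2([[9, 20], [11, 18]])
        assert res.statistic == pytest.approx(0.305, abs=5e-4)
        assert res.df == 1

    def test_proportional_table_zero(self):
        assert chi_square_2x2([[10, 20], [5, 10]]).statistic == pytest.approx(0)

    def test_transpose_invariance(self):
        a = chi_square_2x2([[9, 20], [11, 18]]).statistic
        b = chi_square_2x2([[9, 11], [20, 18]]).statistic
        assert a == pytest.approx(b)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 10]])


class TestSpearman:
    def test_monotone_pair_is_one(self):
        z = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["p1"],
                         columns=list("abcde"))
        scores = pd.DataFrame({"dom": [2.0, 4.0, 6.0, 8.0, 10.0]}, index=list("abcde"))
        out = spearman_with_bh(z, scores)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_tied_example_against_hand_ranked_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([10.0, 9.0, 7.0, 7.0, 5.0, 1.0])
        # independent oracle: average ranks computed explicitly, then Pearson
        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        z = pd.DataFrame([x], index=["p1"], columns=list("abcdef"))
        scores = pd.DataFrame({"dom": y}, index=list("abcdef"))
        out = spearman_with_bh(z, scores)
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_adjusted_hits_subset_of_nominal(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(30, 20)),
            index=[f"p{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(20)],
        )
        scores = pd.DataFrame(
            rng.normal(size=(20, 4)),
            index=z.columns,
            columns=["c1", "c2", "c3", "c4"],
        )
        out = spearman_with_bh(z, scores)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert not (out["adjusted_hit"] & ~out["nominal_hit"]).any()

    def test_constant_input_flagged(self):
        z = pd.DataFrame([[1.0, 1.0, 1.0, 1.0, 1.0]], index=["p1"],
                         columns=list("abcde"))
        scores = pd.DataFrame({"dom": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        out = spearman_with_bh(z, scores)
        assert np.isnan(out["rho"].iloc[0]) and out["flag"].iloc[0] == "constant input"


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = partial_correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref_r, abs=1e-12)
        assert res.p_two_sided == pytest.approx(ref_p, rel=1e-6)

    def test_shared_covariate_drives_marginal_not_partial(self, rng):
        n = 200
        c = rng.normal(size=n)
        x = 2 * c + rng.normal(size=n)
        y = -3 * c + rng.normal(size=n)
        marginal = abs(sps.pearsonr(x, y)[0])
        partial = abs(partial_correlation(x, y, c[:, None]).statistic)
        assert marginal > 0.5
        assert partial < 0.2

    def test_inverse_correlation_matrix_identity(self, rng):
        # oracle: partial r of (0,1) given (2,3) = -P01 / sqrt(P00 P11),
        # with P the inverse of the 4x4 correlation matrix
        data = rng.normal(size=(60, 4))
        data[:, 1] += 0.5 * data[:, 0] + 0.3 * data[:, 2]
        P = np.linalg.inv(np.corrcoef(data.T))
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        res = partial_correlation(data[:, 0], data[:, 1], data[:, 2:])
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [1, 2, 3], np.ones((3, 1)))


class TestManovaPillai:
    def test_single_response_reduces_to_anova_f(self, rng):
        y = rng.normal(size=24)
        g = np.repeat([0.0, 1.0, 2.0], 8)
        # one-way ANOVA with a single numeric predictor = simple regression F
        design = pd.DataFrame({"g": g})
        res = manova_pillai(y, design)
        slope_model = sps.linregress(g, y)
        f_ref = slope_model.rvalue**2 / (1 - slope_model.rvalue**2) * 22
        assert res.statistic == pytest.approx(f_ref, rel=1e-9)

    def test_two_group_consistency_with_hotelling_t2(self, rng):
        n1 = n2 = 10
        p = 3
        Y = np.vstack(
            [rng.normal(0, 1, size=(n1, p)), rng.normal(0.8, 1, size=(n2, p))]
        )
        g = np.array([0.0] * n1 + [1.0] * n2)
        res = manova_pillai(Y, pd.DataFrame({"g": g}))
        d = Y[:n1].mean(axis=0) - Y[n1:].mean(axis=0)
        S = (
            (n1 - 1) * np.cov(Y[:n1].T) + (n2 - 1) * np.cov(Y[n1:].T)
        ) / (n1 + n2 - 2)
        t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.inv(S) @ d
        f_ref = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
        assert res.statistic == pytest.approx(f_ref, rel=1e-8)

    def test_null_p_values_uniform(self):
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            Y = r.normal(size=(20, 3))
            g = r.permutation([0.0] * 10 + [1.0] * 10)
            pvals.append(manova_pillai(Y, pd.DataFrame({"g": g})).p_two_sided)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_many_responses_rejected(self, rng):
        with pytest.raises(ValueError):
            manova_pillai(rng.normal(size=(5, 4)), pd.DataFrame({"g": [0, 1, 0, 1, 0]}))
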