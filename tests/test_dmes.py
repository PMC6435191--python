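"""DMES calling: eBayes prior, moderated t, BH, fold change, filters, scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import polygamma

from ewaskit.dmes import (
    EbayesPrior,
    beta_fold_change,
    bh_adjust,
    call_dmes,
    candidate_region_scan,
    cell_association_filter,
    estimate_ebayes_prior,
    moderated_t_test,
)
from ewaskit.simulate import CELL_TYPES


def _beta_frame(arr, prefix="s"):
    return pd.DataFrame(
        arr,
        index=pd.Index([f"p{i}" for i in range(arr.shape[0])], name="probe_id"),
        columns=[f"{prefix}{i}" for i in range(arr.shape[1])],
    )


class TestEbayesPrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_ebayes_prior(np.full(100, 0.02), residual_df=10)
        assert np.isinf(prior.d0)
        assert prior.s0_sq > 0

    def test_grid_search_oracle_agreement(self, rng):
        # independent oracle: dense grid over d0 solving the same moment match
        m, df, d0_true, s0 = 200, 20, 6.0, 0.05
        sig2 = s0 * d0_true / rng.chisquare(d0_true, size=m)
        s2 = sig2 * rng.chisquare(df, size=m) / df
        prior = estimate_ebayes_prior(s2, df)
        z = np.log(s2)
        evar = z.var(ddof=1) - polygamma(1, df / 2)
        grid = np.linspace(prior.d0 * 0.5, prior.d0 * 2, 200001)
        mismatch = np.abs(polygamma(1, grid / 2) - evar)
        d0_grid = grid[np.argmin(mismatch)]
        assert abs(prior.d0 - d0_grid) / d0_grid < 1e-3  # 3 significant digits

    def test_parameter_recovery(self, rng):
        m, df, d0_true, s0 = 5000, 56, 4.0, 0.02
        sig2 = s0 * d0_true / rng.chisquare(d0_true, size=m)
        s2 = sig2 * rng.chisquare(df, size=m) / df
        prior = estimate_ebayes_prior(s2, df)
        assert 3.2 <= prior.d0 <= 4.8
        assert 0.017 <= prior.s0_sq <= 0.023

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            estimate_ebayes_prior([0.1, 0.2], residual_df=0.5)


class TestModeratedT:
    @pytest.fixture()
    def fixture_50(self, rng, two_group_labels):
        # heteroscedastic rows so the estimated prior df is finite
        scale = np.sqrt(0.02 * 4.0 / rng.chisquare(4.0, size=50))
        beta = _beta_frame(
            np.clip(rng.normal(0.4, scale[:, None], size=(50, 12)), 0.01, 0.99)
        )
        return beta, two_group_labels(6, 6, index=beta.columns)

    def test_d0_zero_limit_equals_pooled_t(self, fixture_50):
        beta, groups = fixture_50
        res = moderated_t_test(beta, groups, EbayesPrior(d0=1e-12, s0_sq=1.0))
        x = beta.iloc[:, :6].to_numpy()
        y = beta.iloc[:, 6:].to_numpy()
        t_ref = sps.ttest_ind(x, y, axis=1).statistic
        np.testing.assert_allclose(res["t_mod"].to_numpy(), t_ref, atol=1e-6)

    def test_d0_infinite_uses_prior_variance_exactly(self, fixture_50):
        beta, groups = fixture_50
        s0_sq = 0.01
        res = moderated_t_test(beta, groups, EbayesPrior(d0=np.inf, s0_sq=s0_sq))
        expected = res["delta"] / np.sqrt(s0_sq * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(res["t_mod"], expected, atol=1e-12)

    def test_direct_formula_transliteration_oracle(self, fixture_50):
        # scalar re-derivation, independent of the vectorized implementation
        beta, groups = fixture_50
        res = moderated_t_test(beta, groups)
        prior = res.attrs["prior"]
        for probe in beta.index:
            x = beta.loc[probe, groups == "IC"].to_numpy()
            y = beta.loc[probe, groups == "BFC"].to_numpy()
            df = len(x) + len(y) - 2
            s2 = (
                sum((v - x.mean()) ** 2 for v in x) + sum((v - y.mean()) ** 2 for v in y)
            ) / df
            s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
            t = (x.mean() - y.mean()) / np.sqrt(s2_post * (1 / len(x) + 1 / len(y)))
            p = 2 * sps.t.sf(abs(t), prior.d0 + df)
            assert abs(t - res.loc[probe, "t_mod"]) < 1e-10
            assert abs(p - res.loc[probe, "p"]) < 1e-10

    def test_degenerate_group_rejected(self, fixture_50):
        beta, _ = fixture_50
        groups = pd.Series(["IC"] + ["BFC"] * 11, index=beta.columns)
        with pytest.raises(ValueError):
            moderated_t_test(beta, groups)


class TestBHAdjust:
    def test_examples(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_adjusted_never_below_nominal(self, rng):
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_order_invariance(self, rng):
        p = rng.uniform(size=101)
        perm = rng.permutation(101)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    @pytest.mark.parametrize(
        "m1, m2, expected",
        [(0.30, 0.25, 1.2), (0.25, 0.30, -1.2), (0.4, 0.4, 1.0)],
    )
    def test_signed_ratio(self, m1, m2, expected):
        assert beta_fold_change(m1, m2) == pytest.approx(expected)

    def test_magnitude_at_least_one(self, rng):
        m1, m2 = rng.uniform(0.01, 0.99, 100), rng.uniform(0.01, 0.99, 100)
        assert (np.abs(beta_fold_change(m1, m2)) >= 1).all()

    def test_zero_mean_floored_with_warning(self):
        with pytest.warns(UserWarning):
            fc = beta_fold_change(0.0, 0.5)
        assert fc < -1


class TestCellAssociationFilter:
    @pytest.fixture()
    def fractions(self, rng):
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(6) * 8, size=30),
            columns=list(CELL_TYPES),
            index=[f"s{i}" for i in range(30)],
        )
        return fr

    def test_perfect_association_removed(self, fractions):
        beta = pd.DataFrame(
            {"assoc": 0.2 + 0.5 * fractions["CD4T"]}, index=fractions.index
        ).T
        removed = cell_association_filter(beta, fractions)
        assert list(removed) == ["assoc"]

    def test_constant_probe_skipped(self, fractions):
        beta = pd.DataFrame({"const": 0.4}, index=fractions.index).T
        assert len(cell_association_filter(beta, fractions)) == 0

    def test_too_few_samples_rejected(self, fractions):
        beta = pd.DataFrame(
            np.full((1, 6), 0.3), index=["p"], columns=fractions.index[:6]
        )
        with pytest.raises(ValueError):
            cell_association_filter(beta, fractions.iloc[:6])


class TestCallDmes:
    def test_direction_bookkeeping_and_partition(self, cohort_small):
        c = cohort_small
        table, cascade = call_dmes(
            c.beta, c.samples["group"], c.truth["true_fractions"]
        )
        hyper = [p for p, s in c.truth["planted_signs"].items() if s > 0]
        called_hyper = table.loc[
            [p for p in hyper if table.loc[p, "is_dmes"]], "direction"
        ]
        assert (called_hyper == "hyper").all()
        assert cascade["n_hyper"] + cascade["n_hypo"] == cascade["n_dmes"]
        dmes = table[table["is_dmes"]]
        assert set(dmes["direction"]) <= {"hyper", "hypo"}

    def test_fc_threshold_monotonicity(self, cohort_small):
        c = cohort_small
        counts = [
            call_dmes(
                c.beta, c.samples["group"], c.truth["true_fractions"], fc_threshold=fc
            )[1]["n_dmes"]
            for fc in (1.0, 1.2, 1.5, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_flag_consistency(self, cohort_small):
        c = cohort_small
        table, _ = call_dmes(c.beta, c.samples["group"], c.truth["true_fractions"])
        expected = (
            table["passed_padj"] & table["passed_fc"] & ~table["removed_by_cell_filter"]
        )
        assert (table["is_dmes"] == expected).all()
        assert (table["p_adj"] >= table["p"] - 1e-15).all()


class TestRegionScan:
    def _setup(self, rng, n_region=10, planted=3, delta=0.15, n1=29, n2=29):
        n_probes = 40
        base = rng.uniform(0.2, 0.6, size=n_probes)
        beta = base[:, None] + rng.normal(0, 0.05, size=(n_probes, n1 + n2))
        beta[:planted, :n1] += delta
        beta = _beta_frame(np.clip(beta, 0.01, 0.99))
        groups = pd.Series(["IC"] * n1 + ["BFC"] * n2, index=beta.columns)
        ann = pd.DataFrame(
            {
                "chromosome": ["chr5"] * n_region + ["chr2"] * (n_probes - n_region),
                "position": np.arange(n_probes) * 100 + 1000,
                "genic_region": "TSS200",
                "cgi_relation": "Island",
                "snp_maf": np.nan,
            },
            index=beta.index,
        )
        results = moderated_t_test(beta, groups)
        return results, ann

    def test_empty_region_yields_zero(self, rng):
        results, ann = self._setup(rng)
        table, count = candidate_region_scan(results, ann, ("chr9", 1, 10**6))
        assert len(table) == 0 and count == 0

    def test_flank_monotonically_grows_region(self, rng):
        results, ann = self._setup(rng)
        t0, _ = candidate_region_scan(results, ann, ("chr5", 1000, 1400), flank=0)
        t1, _ = candidate_region_scan(results, ann, ("chr5", 1000, 1400), flank=2000)
        assert set(t0.index) <= set(t1.index)

    def test_power_to_detect_planted_effects(self):
        # 3 planted probes at delta=0.15 inside a 10-probe region
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            results, ann = self._setup(rng)
            _, count = candidate_region_scan(results, ann, ("chr5", 1, 10**6))
            hits += count >= 3
        assert hits >= 40  # >= 80% of seeds
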