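"""Statistical battery: Box's M, Wilks' lambda MANOVA, protected ANOVAs,
Spearman + FDR, partial correlation, chi-square and cohort summaries."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA as SmMANOVA

from strokeconn.stats import (
    anova_bonferroni, boxs_m, chi_square_2x2, manova_wilks, partial_corr,
    spearman_fdr, subnetwork_battery, summarize_cohort,
)
from strokeconn.synthetic import table1_fixture

import pandas as pd


class TestBoxsM:
    def test_identical_groups_give_zero_m(self, rng):
        X = rng.normal(size=(8, 2))
        res = boxs_m([X, X.copy()])
        assert res["M"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0)

    def test_univariate_hand_computation(self):
        g1 = np.array([[1.0], [2], [3], [4], [5]])
        g2 = np.array([[2.0], [4], [6], [8], [10]])
        res = boxs_m([g1, g2])
        s1, s2 = np.var(g1, ddof=1), np.var(g2, ddof=1)
        sp = (4 * s1 + 4 * s2) / 8
        M = 8 * np.log(sp) - 4 * np.log(s1) - 4 * np.log(s2)
        assert res["M"] == pytest.approx(float(M), rel=1e-12)

    def test_inflated_variance_rejected_well_above_nominal(self, rng):
        # 200 simulations keep the check fast; the effect is enormous at x10
        rejections = 0
        for _ in range(200):
            g1 = rng.normal(size=(50, 2))
            g2 = rng.normal(scale=np.sqrt(10), size=(50, 2))
            if boxs_m([g1, g2])["p"] < 0.001:
                rejections += 1
        assert rejections / 200 > 0.5

    def test_more_variables_than_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            boxs_m([rng.normal(size=(3, 4)), rng.normal(size=(3, 4))])


class TestManova:
    def test_univariate_reduces_to_anova(self):
        g1 = np.array([[1.0], [2], [3]])
        g2 = np.array([[4.0], [5], [6]])
        res = manova_wilks(g1, g2)
        assert res.wilks_lambda == pytest.approx(4 / 17.5, rel=1e-12)
        assert res.f_stat == pytest.approx(13.5, rel=1e-12)
        f, p = sps.f_oneway(g1.ravel(), g2.ravel())
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_equal_means_lambda_one(self, rng):
        X = rng.normal(size=(10, 3))
        res = manova_wilks(X, X + 0.0)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_matches_hotelling_t2(self, rng):
        X1 = rng.normal(size=(12, 4))
        X2 = rng.normal(0.3, 1.0, size=(15, 4))
        res = manova_wilks(X1, X2)
        n1, n2, p = 12, 15, 4
        d = X1.mean(0) - X2.mean(0)
        Sp = ((n1 - 1) * np.cov(X1, rowvar=False)
              + (n2 - 1) * np.cov(X2, rowvar=False)) / (n1 + n2 - 2)
        T2 = (n1 * n2 / (n1 + n2)) * d @ np.linalg.solve(Sp, d)
        F = T2 * (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p)
        assert res.f_stat == pytest.approx(float(F), abs=1e-8)

    def test_matches_statsmodels_wilks(self, rng):
        X1 = rng.normal(size=(10, 3))
        X2 = rng.normal(0.5, 1.0, size=(11, 3))
        res = manova_wilks(X1, X2)
        Y = np.vstack([X1, X2])
        g = np.array([0] * 10 + [1] * 11)
        sm = SmMANOVA(Y, np.column_stack([np.ones(21), g])).mv_test(
            hypotheses=[("g", np.array([[0.0, 1.0]]), None)])
        tab = sm.results["g"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(tab.loc["Wilks' lambda", "Value"]), abs=1e-8)
        assert res.p_value == pytest.approx(
            float(tab.loc["Wilks' lambda", "Pr > F"]), abs=1e-8)

    def test_singular_sscp_raises(self, rng):
        X = rng.normal(size=(4, 6))
        with pytest.raises(ValueError):
            manova_wilks(X, X + 1)


class TestAnova:
    def test_f_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        df = anova_bonferroni(np.concatenate([a, b])[:, None],
                              ["x"] * 10 + ["y"] * 12)
        t = sps.ttest_ind(a, b).statistic
        assert df["F"][0] == pytest.approx(t**2, abs=1e-10)

    def test_hand_example_and_threshold(self):
        m = np.array([[1.0], [2], [3], [4], [5], [6]])
        df = anova_bonferroni(np.tile(m, (1, 3)), ["a"] * 3 + ["b"] * 3, n_tests=3)
        assert df["F"][0] == pytest.approx(13.5, rel=1e-12)
        assert df["p"][0] == pytest.approx(0.0213, abs=2e-4)
        assert df.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 3)
        # p = 0.0213 > 0.0167, so not significant after protection
        assert not df["significant"].any()

    def test_zero_variance_flagged_degenerate(self):
        m = np.array([[1.0], [1], [2], [2]])
        df = anova_bonferroni(m, ["a", "a", "b", "b"])
        assert df["degenerate"][0] and df["p"][0] == 0.0


class TestSpearmanFdr:
    def test_perfect_monotone_rho_one(self):
        met = pd.DataFrame({"m": [1.0, 2, 3, 4, 5]})
        res = spearman_fdr(met, {"s": [10.0, 20, 30, 40, 50]})
        assert res[0].rho == pytest.approx(1.0)

    def test_bh_hand_example(self):
        # engineer three independent pairs with known raw p is fiddly;
        # check the BH arithmetic directly through statsmodels instead
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-12)

    def test_fdr_monotone_and_bounded(self, rng):
        met = pd.DataFrame(rng.normal(size=(13, 6)),
                           columns=[f"r{i}" for i in range(6)])
        res = spearman_fdr(met, {"s": rng.normal(size=13)})
        praw = np.array([r.p_raw for r in res])
        pfdr = np.array([r.p_fdr for r in res])
        assert np.all(pfdr >= praw - 1e-15) and np.all(pfdr <= 1.0)
        order = np.argsort(praw)
        assert np.all(np.diff(pfdr[order]) >= -1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=13)
        y = rng.normal(size=13)
        met = pd.DataFrame({"m": x})
        r1 = spearman_fdr(met, {"s": y})[0].rho
        r2 = spearman_fdr(pd.DataFrame({"m": np.exp(x)}), {"s": y**3})[0].rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_reported_missing(self, rng):
        met = pd.DataFrame({"m": np.ones(8)})
        res = spearman_fdr(met, {"s": rng.normal(size=8)})
        assert np.isnan(res[0].rho)

    def test_exact_permutation_p_close_to_t_approx(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        met = pd.DataFrame({"m": x})
        approx = spearman_fdr(met, {"s": y})[0].p_raw
        exact = spearman_fdr(met, {"s": y}, exact=True)[0].p_raw
        assert abs(exact - approx) < 0.15


class TestPartialCorr:
    def test_independent_control_reduces_to_plain_r(self, rng):
        # orthogonalize z against x and y so r_xz = r_yz = 0 exactly
        x, y = rng.normal(size=40), rng.normal(size=40)
        z = rng.normal(size=40)
        A = np.column_stack([x - x.mean(), y - y.mean()])
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]
        res = partial_corr(x, y, z, method="pearson")
        assert res["partial_r"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_control_equal_to_y_degenerate(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = partial_corr(x, y, y, method="pearson")
        assert np.isnan(res["partial_r"])

    def test_residual_regression_oracle(self, rng):
        x, y, z = rng.normal(size=(3, 25))
        res = partial_corr(x, y, z, method="pearson")
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert res["partial_r"] == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_rank_mode_matches_pearson_on_ranks(self, rng):
        x, y, z = rng.normal(size=(3, 15))
        a = partial_corr(x, y, z, method="spearman")["partial_r"]
        b = partial_corr(sps.rankdata(x), sps.rankdata(y), sps.rankdata(z),
                         method="pearson")["partial_r"]
        assert a == pytest.approx(b, abs=1e-12)


class TestChiSquare:
    def test_gender_table_hand_values(self):
        res = chi_square_2x2(np.array([[12, 1], [6, 7]]))
        assert res["chi2"] == pytest.approx(6.5, rel=1e-12)
        assert res["p_fisher_one_sided"] == pytest.approx(0.0151, abs=2e-4)

    def test_identical_rows_independent(self):
        res = chi_square_2x2(np.array([[5, 5], [5, 5]]))
        assert res["chi2"] == 0.0 and res["p_chi2"] == pytest.approx(1.0)

    def test_fisher_one_sided_matches_hypergeometric_enumeration(self):
        t = np.array([[12, 1], [6, 7]])
        # enumerate tables with fixed margins at least as extreme (X >= 12)
        p = sum(sps.hypergeom(26, 18, 13).pmf(k) for k in range(12, 14))
        res = chi_square_2x2(t)
        assert res["p_fisher_one_sided"] == pytest.approx(p, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[0, 0], [3, 4]]))


class TestCohortSummary:
    def test_printed_means_and_sds(self):
        s = summarize_cohort(table1_fixture())
        assert s["scores"]["arat"]["mean"] == pytest.approx(12.62, abs=5e-3)
        assert s["scores"]["arat"]["sd"] == pytest.approx(6.54, abs=5e-3)
        assert s["scores"]["fma_se"]["mean"] == pytest.approx(15.46, abs=5e-3)
        assert s["scores"]["fma_se"]["sd"] == pytest.approx(4.43, abs=5e-3)
        assert s["scores"]["fma_wh"]["mean"] == pytest.approx(5.85, abs=5e-3)
        assert s["scores"]["fma_wh"]["sd"] == pytest.approx(2.70, abs=5e-3)

    def test_lesion_tabulations(self):
        s = summarize_cohort(table1_fixture())
        loc = s["lesion_location_counts"]
        assert (loc["PUT"], loc["Insula"], loc["RO"]) == (10, 8, 5)
        assert s["lesion_side_counts"] == {"R": 9, "L": 4}

    def test_single_record_sd_missing(self):
        s = summarize_cohort([table1_fixture()[0]])
        assert s["scores"]["arat"]["sd"] is None


def test_subnetwork_battery_shapes(rng):
    from strokeconn.connectome import Parcellation, group_subnetworks
    parc = Parcellation.toy(6)   # 12 ROIs, all six subnetworks x 2 hemispheres
    blocks = group_subnetworks(parc)
    X = rng.normal(size=(26, 12))
    labels = np.array(["stroke"] * 13 + ["healthy"] * 13)
    tab = subnetwork_battery(X, labels, blocks)
    assert len(tab) == 12
    assert set(tab["subnetwork"]) == {"DMN", "ATT", "VRN", "ADN", "SMA", "SN"}
    assert np.all((tab["wilks_lambda"] > 0) & (tab["wilks_lambda"] <= 1.0 + 1e-12))
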