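"""Statistics layer: z-scoring, PCA, normality-routed tests, regression, agreement."""

import numpy as np
import pandas as pd
import pytest

from cardiotwist.errors import DomainError
from cardiotwist.phantom import reference_cohort_config, sample_cohort
from cardiotwist.stats import (
    bland_altman,
    benjamini_hochberg,
    compare_groups,
    group_comparison_report,
    icc,
    normality_route,
    pca,
    univariate_regression,
    zscore,
)


@pytest.fixture(scope="module")
def cohort():
    return sample_cohort(reference_cohort_config(42))


class TestZscore:
    def test_columns_standardized(self, cohort):
        z = zscore(cohort)
        for c in ("lv_peak_circ_strain_pct", "peak_torsion_rate_deg_per_tau"):
            assert abs(z[c].mean()) < 1e-12
            assert abs(z[c].std(ddof=1) - 1.0) < 1e-12

    def test_idempotent(self, cohort):
        z1 = zscore(cohort)
        z2 = zscore(z1)
        cols = [c for c in z1.columns if z1[c].dtype.kind == "f"]
        assert np.allclose(z1[cols].to_numpy(), z2[cols].to_numpy(), atol=1e-10)

    def test_single_subject_rejected(self, cohort):
        with pytest.raises(DomainError):
            zscore(cohort.iloc[:1])

    def test_zero_sd_column_named_in_error(self, cohort):
        bad = cohort.copy()
        bad["flatline"] = 1.0
        with pytest.raises(DomainError, match="flatline"):
            zscore(bad)


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_pc1(self, rng):
        x = rng.normal(0, 1, 40)
        table = pd.DataFrame({"a": x, "b": 2 * x + 5})
        res = pca(table, k=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction(self, rng):
        X = rng.normal(0, 1, (30, 4))
        table = pd.DataFrame(X, columns=list("abcd"))
        res = pca(table, k=4)
        Z = zscore(table)[list("abcd")].to_numpy()
        recon = res.scores @ res.loadings.T + Z.mean(axis=0)
        assert np.abs(recon - Z).max() < 1e-8

    def test_matches_scikit_learn(self, cohort):
        from sklearn.decomposition import PCA as SKPCA

        cols = [c for c in cohort.columns if c.endswith("_pct")]
        res = pca(cohort, k=3, columns=cols)
        Z = zscore(cohort, cols)[cols].to_numpy()
        sk = SKPCA(n_components=3).fit(Z)
        # compare up to per-component sign
        for j in range(3):
            dot = abs(np.dot(res.loadings[:, j], sk.components_[j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(
            res.explained_variance_ratio,
            sk.explained_variance_ratio_[:3] * (len(Z) - 1) / (len(Z) - 1),
            atol=1e-8,
        )

    def test_scores_centered_with_diagonal_covariance(self, cohort):
        res = pca(cohort, k=3)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-10
        cov = np.cov(res.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10

    def test_k_out_of_range_rejected(self, cohort):
        with pytest.raises(DomainError):
            pca(cohort, k=50)


class TestGroupComparison:
    def test_identical_groups_t_stat_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        cmp_ = compare_groups(x, list(x), route="ttest")
        assert cmp_.statistic == pytest.approx(0.0)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_uniform_sample_routed_to_mannwhitney(self, rng):
        a = rng.uniform(0, 1, 500)
        b = rng.normal(0, 1, 50)
        assert normality_route(a, b) == "mannwhitney"

    def test_gaussian_samples_routed_to_ttest(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        assert normality_route(a, b) == "ttest"

    def test_symmetry_in_group_order(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1.3, 25)
        c1 = compare_groups(a, b, route="ttest")
        c2 = compare_groups(b, a, route="ttest")
        assert c1.statistic == pytest.approx(-c2.statistic)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_small_group_rejected(self):
        with pytest.raises(DomainError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_power_at_study_group_parameters(self):
        """Sham-like vs banded-like torsion rates (4.2+-1.4, n=9 vs 0.84+-0.6,
        n=12) reject at alpha=0.05 in at least 95% of seeded draws."""
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            a = r.normal(4.2, 1.4, 9)
            b = r.normal(0.84, 0.6, 12)
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep >= 0.95


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = univariate_regression(x, 2 * x)
        assert r.slope == pytest.approx(2.0)
        assert r.r == pytest.approx(1.0)

    def test_null_correlation_small(self, rng):
        x = rng.normal(0, 1, 10000)
        y = rng.normal(0, 1, 10000)
        r = univariate_regression(x, y)
        assert abs(r.r) < 0.05

    def test_r_squared_identity(self, rng):
        x = rng.normal(0, 1, 60)
        y = 1.3 * x + rng.normal(0, 0.8, 60)
        res = univariate_regression(x, y)
        pred = res.slope * x + res.intercept
        ss_reg = np.sum((pred - y.mean()) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert res.r**2 == pytest.approx(ss_reg / ss_tot, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(DomainError):
            univariate_regression([1.0] * 5, [1, 2, 3, 4, 5])


class TestAgreement:
    def test_identical_raters(self):
        x = [1.0, 2.0, 3.0, 4.5, 5.0]
        assert icc(x, list(x)).icc == pytest.approx(1.0)
        ba = bland_altman(x, list(x))
        assert ba.mean_difference == pytest.approx(0.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x + 1, x)
        assert ba.mean_difference == pytest.approx(1.0)
        assert ba.sd_difference == pytest.approx(0.0)

    def test_icc_matches_anova_oracle(self):
        """Brute-force two-way ANOVA table on a 5-pair toy set."""
        r1 = np.array([9.0, 10.0, 12.0, 8.0, 11.0])
        r2 = np.array([9.5, 10.5, 11.0, 8.5, 12.0])
        data = np.column_stack([r1, r2])
        n, k = data.shape
        grand = data.mean()
        ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand
        ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
        expect = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        assert icc(r1, r2).icc == pytest.approx(expect, abs=1e-12)

    def test_icc_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(0)
        r1 = rng.normal(10, 2, 12)
        r2 = r1 + rng.normal(0.3, 0.8, 12)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": ["a", "b"] * 12,
                "score": np.column_stack([r1, r2]).ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc_a1 = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(r1, r2).icc == pytest.approx(icc_a1, abs=1e-9)

    def test_confidence_interval_brackets_mean_difference(self, rng):
        r1 = rng.normal(0, 1, 8)
        r2 = r1 + rng.normal(0.85, 0.9, 8)
        ba = bland_altman(r2, r1)
        assert ba.ci_lower <= ba.mean_difference <= ba.ci_upper
        assert ba.loa_lower < ba.ci_lower and ba.ci_upper < ba.loa_upper

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            icc([1, 2, 3], [1, 2])


class TestHelpers:
    def test_benjamini_hochberg_monotone(self):
        p = np.array([0.001, 0.02, 0.03, 0.5])
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_group_comparison_report_covers_pairs(self, cohort):
        rep = group_comparison_report(cohort)
        assert set(zip(rep["group_a"], rep["group_b"])) == {("control", "pah"), ("sham", "pab")}
        assert (rep["p_value"] <= 1).all() and (rep["p_value"] >= 0).all()
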