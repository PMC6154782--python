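"""Variant QC, scan engines vs independent fits, inflation and h2 machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import restaq
from restaq.datatypes import GenotypeMatrix
from restaq.gwas import CHI2_NULL_MEDIAN, hwe_test


def _matrix_from_dosages(d, info=None):
    d = np.asarray(d, dtype=float)
    m = d.shape[1]
    variants = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": np.arange(1, m + 1),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "info": np.ones(m) if info is None else np.asarray(info, float),
        }
    )
    ids = np.array([f"S{i}" for i in range(d.shape[0])], dtype=object)
    return GenotypeMatrix(ids, variants, d)


class TestVariantQC:
    def test_exact_hwe_proportions_kept(self):
        d = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        g = _matrix_from_dosages(d[:, None])
        kept, stats_df = restaq.variant_qc(g)
        assert kept.n_variants == 1
        assert stats_df["hwe_p"].iloc[0] == pytest.approx(1.0)

    def test_rare_variant_removed_on_maf(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.995, size=(2000, 1)).astype(float)
        g = _matrix_from_dosages(d)
        kept, stats_df = restaq.variant_qc(g)
        assert kept.n_variants == 0
        assert stats_df["fail_reason"].iloc[0] == "maf"

    def test_low_info_removed(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(500, 2)).astype(float)
        g = _matrix_from_dosages(d, info=[0.79, 0.95])
        kept, stats_df = restaq.variant_qc(g)
        assert list(stats_df["kept"]) == [False, True]
        assert stats_df["fail_reason"].iloc[0] == "info"

    def test_hwe_violation_removed(self):
        # all heterozygotes: gross HWE violation at f=0.5
        d = np.ones((2000, 1))
        g = _matrix_from_dosages(d)
        kept, stats_df = restaq.variant_qc(g)
        assert kept.n_variants == 0
        assert stats_df["fail_reason"].iloc[0] == "hwe"

    def test_monomorphic_removed_with_maf_reason(self):
        g = _matrix_from_dosages(np.zeros((100, 1)))
        kept, stats_df = restaq.variant_qc(g)
        assert kept.n_variants == 0
        assert stats_df["fail_reason"].iloc[0] == "maf"

    def test_idempotent_and_order_independent(self):
        g = restaq.gen_genotypes(800, 60, (0.005, 0.5), seed=3,
                                 info_range=(0.6, 1.0))
        once, _ = restaq.variant_qc(g)
        twice, stats2 = restaq.variant_qc(once)
        assert twice.n_variants == once.n_variants
        assert stats2["kept"].all()
        perm = np.random.default_rng(4).permutation(g.n_variants)
        kept_perm, _ = restaq.variant_qc(g.take_variants(perm))
        assert set(kept_perm.variants["snp"]) == set(once.variants["snp"])

    def test_hwe_null_rejection_rate(self):
        g = restaq.gen_genotypes(1500, 20000, (0.1, 0.5), seed=5)
        p = hwe_test(g.dosages)
        # alpha=1e-3 gives a measurable expected count (20 of 20000)
        assert (p < 1e-3).mean() == pytest.approx(1e-3, abs=7e-4)

    def test_exact_hwe_matches_chi2_roughly(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, size=(500, 20)).astype(float)
        p_exact = hwe_test(d, exact=True)
        p_chi2 = hwe_test(d, exact=False)
        assert np.corrcoef(p_exact, p_chi2)[0, 1] > 0.9


class TestLogisticScan:
    def test_two_by_two_closed_form(self):
        # exposure x case table (a,b,c,d) = (40,60,20,80)
        g1 = np.repeat([1.0, 1.0, 0.0, 0.0], [40, 60, 20, 80])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [40, 60, 20, 80])
        res = restaq.logistic_scan(_matrix_from_dosages(g1[:, None]), y)
        log_or = np.log(40 * 80 / (60 * 20))
        se = np.sqrt(1 / 40 + 1 / 60 + 1 / 20 + 1 / 80)
        assert res.table["effect"].iloc[0] == pytest.approx(log_or, abs=1e-8)
        assert res.table["se"].iloc[0] == pytest.approx(se, abs=1e-8)

    def test_matches_statsmodels_with_covariates(self, small_cohort):
        g, cov = small_cohort
        rng = np.random.default_rng(7)
        y = (rng.random(g.n_samples) < 0.35).astype(float)
        cols = ["age", "sex", "PC1", "PC2"]
        res = restaq.logistic_scan(g, y, cov[cols])
        for j in [0, 10, 49]:
            X = sm.add_constant(
                np.column_stack([g.dosages[:, j], cov[cols].to_numpy()])
            )
            fit = sm.Logit(y, X).fit(disp=0)
            assert res.table["effect"].iloc[j] == pytest.approx(
                fit.params[1], abs=1e-8
            )
            assert res.table["se"].iloc[j] == pytest.approx(fit.bse[1], abs=1e-8)

    def test_single_class_raises(self, small_cohort):
        g, _ = small_cohort
        with pytest.raises(ValueError):
            restaq.logistic_scan(g, np.ones(g.n_samples))

    def test_separation_flagged_not_crashed(self):
        g1 = np.repeat([0.0, 2.0], [50, 50])
        y = np.repeat([0.0, 1.0], [50, 50])  # perfectly separated
        res = restaq.logistic_scan(_matrix_from_dosages(g1[:, None]), y)
        row = res.table.iloc[0]
        assert row["fail_reason"] in ("separation", "nonconverged")
        assert np.isnan(row["effect"])

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(8)
        n = 4000
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        eta = -1.5 + 0.4 * g[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = restaq.logistic_scan(_matrix_from_dosages(g), y)
        assert res.table["effect"].iloc[0] == pytest.approx(0.4, abs=0.15)


class TestLinearScan:
    def test_exact_fit_when_noiseless(self, small_cohort):
        g, _ = small_cohort
        y = 0.7 * g.dosages[:, 3] + 2.0
        res = restaq.linear_scan(g, y)
        assert res.table["effect"].iloc[3] == pytest.approx(0.7, abs=1e-10)
        assert res.table["p"].iloc[3] < 1e-200

    def test_matches_statsmodels_ols(self, small_cohort):
        g, cov = small_cohort
        rng = np.random.default_rng(9)
        y = rng.standard_normal(g.n_samples)
        cols = ["age", "sex", "townsend"]
        res = restaq.linear_scan(g, y, cov[cols])
        for j in [1, 25]:
            X = sm.add_constant(
                np.column_stack([g.dosages[:, j], cov[cols].to_numpy()])
            )
            fit = sm.OLS(y, X).fit()
            assert res.table["effect"].iloc[j] == pytest.approx(
                fit.params[1], abs=1e-10
            )
            assert res.table["se"].iloc[j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert res.table["p"].iloc[j] == pytest.approx(
                fit.pvalues[1], rel=1e-8
            )

    def test_zero_variance_phenotype_raises(self, small_cohort):
        g, _ = small_cohort
        with pytest.raises(ValueError):
            restaq.linear_scan(g, np.full(g.n_samples, 3.0))

    def test_null_lambda_near_one(self):
        g = restaq.gen_genotypes(1500, 3000, (0.1, 0.5), seed=10)
        y = np.random.default_rng(11).standard_normal(1500)
        res = restaq.linear_scan(g, y)
        assert res.lambda_gc == pytest.approx(1.0, abs=0.05)


class TestGenomicInflation:
    def test_definition(self):
        assert restaq.genomic_inflation(
            chi2=np.full(11, CHI2_NULL_MEDIAN)
        ) == pytest.approx(1.0)

    def test_scale_equivariance(self):
        chi2 = np.random.default_rng(12).chisquare(1, size=999)
        lam = restaq.genomic_inflation(chi2=chi2)
        assert restaq.genomic_inflation(chi2=2 * chi2) == pytest.approx(
            2 * lam, rel=1e-12
        )

    def test_uniform_pvalues(self):
        # exactly uniform grid of 1e5 p-values -> lambda = 1 by definition;
        # a random uniform draw agrees within 3 sigma of the median's
        # sampling noise (~0.0074 at this size)
        n = 100_000
        grid = (np.arange(n) + 0.5) / n
        assert restaq.genomic_inflation(p=grid) == pytest.approx(1.0, abs=1e-6)
        p = np.random.default_rng(13).random(n)
        assert restaq.genomic_inflation(p=p) == pytest.approx(1.0, abs=0.025)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            restaq.genomic_inflation(chi2=np.array([]))


class TestH2Regression:
    def test_noiseless_exact_recovery(self):
        ell = np.linspace(1, 80, 2000)
        N, M = 30000, 2000
        chi2 = 1 + N * 0.25 * ell / M
        h2, se, intercept = restaq.h2_regression(chi2, ell, N, M)
        assert h2 == pytest.approx(0.25, abs=1e-10)
        assert intercept == pytest.approx(1.0, abs=1e-10)

    def test_parameterisation_invariance_in_n(self):
        ell = np.linspace(1, 50, 500)
        M = 500
        for N in (10000, 20000):
            chi2 = 1 + N * 0.1 * ell / M
            h2, *_ = restaq.h2_regression(chi2, ell, N, M)
            assert h2 == pytest.approx(0.1, abs=1e-10)

    def test_null_coverage(self):
        rng = np.random.default_rng(14)
        ell = rng.uniform(1, 100, 3000)
        hits = 0
        for _ in range(50):
            chi2 = rng.standard_normal(3000) ** 2
            h2, se, _ = restaq.h2_regression(chi2, ell, 40000, 3000)
            hits += abs(h2) <= 2 * se
        assert hits >= 45

    def test_constant_ld_scores_raise(self):
        with pytest.raises(ValueError):
            restaq.h2_regression(np.ones(10), np.ones(10), 100, 10)

    def test_scan_level_constant_ld_estimator(self):
        # chi2 with mean 1 + N*h2/M recovers h2 in the closed form
        rng = np.random.default_rng(15)
        N, M, h2 = 20000, 4000, 0.2
        lam = 1 + N * h2 / M
        g = restaq.gen_genotypes(400, 4, (0.2, 0.5), seed=16)
        res = restaq.linear_scan(g, rng.standard_normal(400))
        chi2 = rng.chisquare(1, M) * lam
        est = (chi2.mean() - 1) * M / N
        assert est == pytest.approx(h2, abs=0.05)
        assert res.h2_estimate()[0] is not None  # API smoke


class TestGenomeWideLabel:
    def test_threshold_constant(self):
        assert restaq.GENOME_WIDE_P == 5e-8

    def test_counting(self, small_cohort):
        g, _ = small_cohort
        y = 5.0 * g.dosages[:, 0] + 0.01 * np.random.default_rng(17).standard_normal(
            g.n_samples
        )
        res = restaq.linear_scan(g, y)
        assert res.n_genome_wide >= 1
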