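"""Polygenic scoring, quantile contrasts and BH FDR."""

import numpy as np
import pandas as pd
import pytest

import restaq
from restaq.datatypes import GenotypeMatrix
from restaq.prs import DEFAULT_THRESHOLDS, PRSConfig, quantile_groups


def _geno(dosages, chrom=None, pos=None, ref=None, alt=None):
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    variants = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else np.arange(1, m + 1),
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "info": np.ones(m),
        }
    )
    ids = np.array([f"S{i}" for i in range(d.shape[0])], dtype=object)
    return GenotypeMatrix(ids, variants, d)


def _sumstats(g, beta, p, swap=None):
    v = g.variants
    swap = np.zeros(len(v), dtype=bool) if swap is None else swap
    return pd.DataFrame(
        {
            "SNP": v["snp"],
            "CHR": v["chrom"],
            "BP": v["pos"],
            "A1": np.where(swap, v["ref"], v["alt"]),
            "A2": np.where(swap, v["alt"], v["ref"]),
            "BETA": np.where(swap, -np.asarray(beta), beta),
            "P": p,
        }
    )


class TestComputePRS:
    def test_single_snp_arithmetic(self):
        g = _geno(np.array([[0.0], [1.0], [2.0]]))
        ss = _sumstats(g, [np.log(2)], [1e-9])
        scores, rep = restaq.compute_prs(ss, g, 5e-8)
        assert np.allclose(scores, [0.0, np.log(2), 2 * np.log(2)])
        assert rep["n_used"] == 1 and not rep["empty"]

    def test_allele_flip_invariance(self):
        # re-expressing every *target* variant on the opposite strand
        # orientation (ref/alt swapped, dosage -> 2 - dosage) leaves the
        # effect-allele-matched scores unchanged
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(50, 8)).astype(float)
        g = _geno(d)
        beta = rng.standard_normal(8)
        p = rng.random(8) * 0.4
        ss = _sumstats(g, beta, p)
        direct, _ = restaq.compute_prs(ss, g, 0.5)
        g_flip = _geno(2.0 - d, ref=["G"] * 8, alt=["A"] * 8)
        flipped, rep = restaq.compute_prs(ss, g_flip, 0.5)
        assert rep["n_flipped"] == 8
        assert np.allclose(direct, flipped, atol=1e-12)

    def test_brute_force_resummation(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, rng.uniform(0.05, 0.5, 30), size=(100, 30)).astype(float)
        g = _geno(d)
        beta = rng.standard_normal(30)
        p = rng.random(30)
        for thr in DEFAULT_THRESHOLDS:
            scores, _ = restaq.compute_prs(_sumstats(g, beta, p), g, thr)
            sel = p < thr
            expected = d[:, sel] @ beta[sel]
            assert np.allclose(scores, expected, atol=1e-12)

    def test_linearity_over_variant_sets(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(40, 10)).astype(float)
        g = _geno(d)
        beta = rng.standard_normal(10)
        p = np.full(10, 1e-4)
        whole, _ = restaq.compute_prs(_sumstats(g, beta, p), g, 0.5)
        a = g.take_variants(np.arange(5))
        b = g.take_variants(np.arange(5, 10))
        sa, _ = restaq.compute_prs(_sumstats(g, beta, p).iloc[:5], a, 0.5)
        sb, _ = restaq.compute_prs(_sumstats(g, beta, p).iloc[5:], b, 0.5)
        assert np.allclose(whole, sa + sb, atol=1e-12)

    def test_unmatchable_variant_skipped(self):
        g = _geno(np.array([[1.0]]))
        ss = _sumstats(g, [0.5], [1e-9])
        ss.loc[0, "A1"] = "T"  # neither allele matches
        scores, rep = restaq.compute_prs(ss, g, 0.5)
        assert rep["n_unmatched"] == 1 and rep["empty"]
        assert np.all(scores == 0.0)


class TestQuantileGroups:
    def test_quartiles_balanced(self):
        scores = np.random.default_rng(3).standard_normal(101)
        labels, q, fallback = quantile_groups(scores, 4)
        sizes = np.bincount(labels)
        assert q == 4 and not fallback
        assert sizes.max() - sizes.min() <= 1
        assert scores[labels == 3].min() >= scores[labels == 0].max()

    def test_three_distinct_values_fall_back_to_tertiles(self):
        scores = np.random.default_rng(4).choice([0.0, 0.3, 0.6], size=60)
        labels, q, fallback = quantile_groups(scores, 4)
        assert q == 3 and fallback
        # groups are exactly the distinct values
        for lab, val in enumerate([0.0, 0.3, 0.6]):
            assert np.all(scores[labels == lab] == val)

    def test_degenerate_scores_raise(self):
        with pytest.raises(ValueError):
            quantile_groups(np.zeros(10), 4)


class TestQuantileContrast:
    def test_null_coverage(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for _ in range(reps):
            scores = rng.standard_normal(400)
            y = (rng.random(400) < 0.3).astype(float)
            row = restaq.quantile_contrast(scores, y, n_quantiles=4)
            hits += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert hits / reps == pytest.approx(0.95, abs=0.04)

    def test_signal_detected(self):
        rng = np.random.default_rng(6)
        n = 20000
        scores = rng.standard_normal(n)
        liab = scores + rng.standard_normal(n)
        y = (liab > np.quantile(liab, 0.7)).astype(float)
        row = restaq.quantile_contrast(scores, y, n_quantiles=4)
        assert row["estimate"] > 1.0 and row["p"] < 0.05

    def test_continuous_outcome_uses_beta(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(500)
        y = 0.5 * scores + rng.standard_normal(500)
        row = restaq.quantile_contrast(scores, y, n_quantiles=4)
        assert row["measure"] == "beta" and row["estimate"] > 0

    def test_fallback_recorded(self):
        rng = np.random.default_rng(8)
        scores = rng.choice([0.0, 1.0, 2.0], size=200)
        y = (rng.random(200) < 0.4).astype(float)
        row = restaq.quantile_contrast(scores, y, n_quantiles=4)
        assert row["fallback"] and row["n_quantiles_used"] == 3


class TestFDR:
    def test_step_up_hand_computation(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        adj = restaq.fdr_adjust(p)
        assert np.allclose(adj, 0.05)

    def test_single_p_unchanged(self):
        assert restaq.fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(30)
        adj = restaq.fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_empty_family(self):
        assert restaq.fdr_adjust([]).size == 0

    def test_manual_bh_oracle(self):
        rng = np.random.default_rng(10)
        p = rng.random(17)
        m = p.size
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            manual[idx] = running
        assert np.allclose(restaq.fdr_adjust(p), manual)


class TestPRSQuantileModel:
    def test_table_shape_and_fdr_family(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.3, size=(400, 40)).astype(float)
        g = _geno(d)
        beta = rng.standard_normal(40) * 0.1
        p = rng.random(40)
        ss = _sumstats(g, beta, p)
        ss["P"] = np.clip(ss["P"], 1e-12, 1.0)
        outcomes = pd.DataFrame(
            {"mood_instability": (rng.random(400) < 0.4).astype(float),
             "neuroticism": rng.integers(0, 13, 400).astype(float)}
        )
        cfg = PRSConfig(thresholds=(0.05, 0.1, 0.5))
        res = restaq.PRSQuantileModel(ss, g, outcomes, config=cfg).fit()
        assert len(res.table) == 6  # 3 thresholds x 2 outcomes
        for out, grp in res.table.groupby("outcome"):
            ok = grp.dropna(subset=["p"])
            assert np.all(ok["p_fdr"].to_numpy() >= ok["p"].to_numpy() - 1e-15)
        assert set(res.table["measure"]) == {"OR", "beta"}

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            PRSConfig(thresholds=(0.5, 0.1))
        with pytest.raises(ValueError):
            PRSConfig(thresholds=(0.0, 0.5))
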