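"""Variant QC and additive per-variant association scans.

Variant QC mirrors the standard imputed-GWAS filters: imputation
INFO >= 0.8, minor-allele frequency >= 0.01 and Hardy-Weinberg
equilibrium p >= 1e-6 (1-df chi-square on hard genotype calls).  The scan
fits, per variant, an additive model of the phenotype on alt-allele
dosage plus covariates: maximum-likelihood logistic regression for the
binary low-RA phenotype, OLS for continuous RA.  Scan-level diagnostics
are the genomic-control inflation factor (median chi-square over the null
median) and a SNP-heritability estimate from an LD-score-style regression
of per-variant chi-square statistics.

Organised statsmodels-style: :class:`AssociationScan` is the model,
``fit()`` returns an :class:`AssociationScanResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import GenotypeMatrix

__all__ = [
    "variant_qc",
    "hwe_test",
    "AssociationScan",
    "AssociationScanResults",
    "logistic_scan",
    "linear_scan",
    "genomic_inflation",
    "h2_regression",
    "LDScoreRegression",
    "GENOME_WIDE_P",
    "CHI2_NULL_MEDIAN",
]

#: genome-wide significance threshold for a single-variant test
GENOME_WIDE_P = 5e-8

#: median of the 1-df chi-square distribution
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.454936...


# ---------------------------------------------------------------------------
# variant QC


def hwe_test(dosages: np.ndarray, exact: bool = False) -> np.ndarray:
    """Hardy-Weinberg p-value per variant from hard genotype calls.

    Dosages are rounded to the nearest integer genotype.  The default test
    is the continuity-free 1-df chi-square on observed vs expected
    genotype counts; ``exact=True`` uses the conditional exact test
    (probability-mass method), summing the probabilities of all
    heterozygote counts no more likely than the observed one.
    """
    d = np.asarray(dosages)
    if d.ndim == 1:
        d = d[:, None]
    g = np.rint(d).astype(np.int64)
    n = g.shape[0]
    n2 = (g == 2).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n0 = n - n1 - n2
    if exact:
        return np.array(
            [_hwe_exact(a, b, c) for a, b, c in zip(n0, n1, n2)]
        )
    p = (n1 + 2 * n2) / (2 * n)
    exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(
            axis=0
        )
    pval = stats.chi2.sf(chi2, df=1)
    pval[(p == 0) | (p == 1)] = 1.0  # monomorphic: nothing to test
    return pval


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test (sum of heterozygote-count probabilities <= observed)."""
    n = n0 + n1 + n2
    na = n1 + 2 * min(n0, n2)  # minor-allele count after orienting
    if na == 0 or n == 0:
        return 1.0
    from scipy.special import gammaln

    hets = np.arange(na % 2, na + 1, 2)
    homr = (na - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(na + 1)
        + gammaln(2 * n - na + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n1][0]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def variant_qc(
    g: GenotypeMatrix,
    info_min: float = 0.8,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    exact_hwe: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants on INFO, MAF and HWE.

    Keeps variants with ``info >= info_min``, ``MAF >= maf_min`` (MAF from
    mean dosage) and HWE p ``>= hwe_alpha``.  Monomorphic variants fall to
    the MAF filter.  Idempotent and order-independent.

    Returns the filtered matrix and a per-variant stats table
    (``maf``, ``hwe_p``, ``info``, ``kept``, ``fail_reason``).
    """
    maf = g.maf()
    info = g.variants["info"].to_numpy(float)
    hwe_p = (
        hwe_test(g.dosages, exact=exact_hwe)
        if g.n_variants
        else np.empty(0)
    )
    fail = np.full(g.n_variants, "", dtype=object)
    fail[hwe_p < hwe_alpha] = "hwe"
    fail[maf < maf_min] = "maf"
    fail[info < info_min] = "info"
    kept = fail == ""
    stats_df = pd.DataFrame(
        {
            "snp": g.variants["snp"].to_numpy(),
            "maf": maf,
            "hwe_p": hwe_p,
            "info": info,
            "kept": kept,
            "fail_reason": fail,
        }
    )
    return g.take_variants(np.flatnonzero(kept)), stats_df


# ---------------------------------------------------------------------------
# logistic IRLS core


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _logit_fit(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxit: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson (IRLS) logistic fit.

    Returns (beta, cov, converged); after the log-likelihood change drops
    below ``tol`` one extra Newton step polishes the solution to machine
    precision (quadratic convergence).
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    ll = _loglik(X @ beta, y)
    converged = False
    for _ in range(maxit):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            return beta, np.full((k, k), np.nan), False
        # step-halving line search
        new_beta = beta + step
        new_ll = _loglik(X @ new_beta, y)
        halvings = 0
        while new_ll < ll - 1e-10 and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X @ new_beta, y)
            halvings += 1
        done = abs(new_ll - ll) < tol
        beta, ll = new_beta, new_ll
        if done:
            # one polishing Newton step
            eta = X @ beta
            mu = expit(eta)
            w = mu * (1.0 - mu)
            XtWX = X.T @ (X * w[:, None])
            try:
                beta = beta + np.linalg.solve(XtWX, X.T @ (y - mu))
                eta = X @ beta
                mu = expit(eta)
                w = mu * (1.0 - mu)
                XtWX = X.T @ (X * w[:, None])
            except np.linalg.LinAlgError:
                pass
            converged = True
            break
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, cov, converged


def _design(
    covariates: pd.DataFrame | np.ndarray | None, n: int
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix, with a full-rank check."""
    if covariates is None:
        return np.ones((n, 1)), ["const"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"x{j}" for j in range(C.shape[1])]
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    return X, ["const"] + names


# ---------------------------------------------------------------------------
# the scan model


class AssociationScan:
    """Per-variant additive association scan.

    Parameters
    ----------
    endog : array-like
        Phenotype: binary 0/1 for ``family='logistic'`` (the low-RA
        case/control trait), continuous for ``family='linear'``.  NaN
        entries drop the sample from every fit.
    genotypes : GenotypeMatrix
        Post-QC dosages.
    covariates : DataFrame or array, optional
        Adjustment covariates (an intercept is always added).
    family : {'logistic', 'linear'}

    ``fit()`` returns an :class:`AssociationScanResults`.
    """

    def __init__(
        self,
        endog,
        genotypes: GenotypeMatrix,
        covariates=None,
        family: str = "logistic",
    ):
        if family not in ("logistic", "linear"):
            raise ValueError("family must be 'logistic' or 'linear'")
        y = np.asarray(endog, dtype=float)
        if y.shape[0] != genotypes.n_samples:
            raise ValueError("phenotype length does not match sample count")
        keep = ~np.isnan(y)
        if covariates is not None:
            cov_arr = (
                covariates.to_numpy(float)
                if isinstance(covariates, pd.DataFrame)
                else np.asarray(covariates, dtype=float)
            )
            keep &= ~np.isnan(cov_arr).any(axis=1 if cov_arr.ndim > 1 else 0)
        self._keep = keep
        self.endog = y[keep]
        self.genotypes = genotypes
        self.family = family
        if isinstance(covariates, pd.DataFrame):
            covariates = covariates.iloc[np.flatnonzero(keep)].reset_index(drop=True)
        elif covariates is not None:
            covariates = np.asarray(covariates, dtype=float)[keep]
        self.covariates = covariates
        self.nobs = int(keep.sum())
        if family == "logistic":
            u = np.unique(self.endog)
            if not np.all(np.isin(u, [0.0, 1.0])):
                raise ValueError("logistic scan needs a 0/1 phenotype")
            if u.size < 2:
                raise ValueError("need both cases and controls")
        else:
            if np.std(self.endog) == 0:
                raise ValueError("zero-variance continuous phenotype")

    def fit(self, tol: float = 1e-8, maxit: int = 50) -> "AssociationScanResults":
        G = self.genotypes.dosages[self._keep, :]
        C, _ = _design(self.covariates, self.nobs)
        if self.family == "logistic":
            table = self._fit_logistic(G, C, tol, maxit)
        else:
            table = self._fit_linear(G, C)
        meta = self.genotypes.variants.reset_index(drop=True)
        out = pd.concat(
            [meta[["snp", "chrom", "pos", "ref", "alt", "info"]], table], axis=1
        )
        return AssociationScanResults(self, out)

    def _fit_logistic(self, G, C, tol, maxit):
        y = self.endog
        n, kc = C.shape
        beta_null, _, _ = _logit_fit(C, y, tol=tol, maxit=maxit)
        m = G.shape[1]
        eff = np.full(m, np.nan)
        se = np.full(m, np.nan)
        reasons = np.full(m, "", dtype=object)
        X = np.empty((n, kc + 1))
        X[:, 1:] = C
        warm = np.zeros(kc + 1)
        warm[1:] = beta_null
        for j in range(m):
            g = G[:, j]
            if np.std(g) == 0:
                reasons[j] = "monomorphic"
                continue
            X[:, 0] = g
            beta, cov, converged = _logit_fit(X, y, beta0=warm, tol=tol, maxit=maxit)
            if not converged:
                reasons[j] = "nonconverged"
                continue
            if abs(beta[0]) > 15 or not np.isfinite(cov[0, 0]) or cov[0, 0] <= 0:
                reasons[j] = "separation"
                continue
            eff[j] = beta[0]
            se[j] = np.sqrt(cov[0, 0])
        z = eff / se
        p = 2 * stats.norm.sf(np.abs(z))
        return self._assemble(G, eff, se, z, p, reasons)

    def _fit_linear(self, G, C):
        y = self.endog
        n, kc = C.shape
        # Frisch-Waugh: residualise phenotype and dosages on covariates
        Q, _ = np.linalg.qr(C)
        y_res = y - Q @ (Q.T @ y)
        G_res = G - Q @ (Q.T @ G)
        gg = np.einsum("ij,ij->j", G_res, G_res)
        gy = G_res.T @ y_res
        df = n - kc - 1
        reasons = np.full(G.shape[1], "", dtype=object)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            rss = np.maximum(y_res @ y_res - beta**2 * gg, 0.0)
            sigma2 = rss / df
            se = np.sqrt(sigma2 / gg)
        mono = gg <= 1e-12 * n
        beta[mono] = np.nan
        se[mono] = np.nan
        reasons[mono] = "monomorphic"
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        p = 2 * stats.t.sf(np.abs(z), df=df)
        return self._assemble(G, beta, se, z, p, reasons)

    def _assemble(self, G, eff, se, z, p, reasons):
        f = G.mean(axis=0) / 2.0 if G.size else np.empty(0)
        return pd.DataFrame(
            {
                "effect": eff,
                "se": se,
                "z": z,
                "p": p,
                "maf": np.minimum(f, 1 - f),
                "hwe_p": hwe_test(G) if G.size else np.empty(0),
                "n": self.nobs,
                "fail_reason": reasons,
            }
        )


class AssociationScanResults:
    """Results of an :class:`AssociationScan` fit.

    ``table`` holds one row per variant (effect = log-odds or beta per
    alt-allele dose, Wald SE/z/p, MAF, HWE p, n, failure reason).
    Scan-level diagnostics: ``lambda_gc`` and the constant-LD
    SNP-heritability estimate ``h2`` (see :func:`h2_regression` for the
    varying-LD regression).
    """

    def __init__(self, model: AssociationScan, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def ok(self) -> pd.DataFrame:
        return self.table[self.table["fail_reason"] == ""]

    @property
    def chi2(self) -> np.ndarray:
        return (self.ok["z"].to_numpy() ** 2).astype(float)

    @property
    def lambda_gc(self) -> float:
        return genomic_inflation(chi2=self.chi2)

    def h2_estimate(self) -> tuple[float, float]:
        """SNP heritability for independent variants (constant LD scores).

        With mutually independent variants every LD score is 1, so the
        LD-score regression slope degenerates to the closed form
        ``h2 = (mean(chi2) - 1) * M / N``; the SE comes from the sampling
        variance of the mean chi-square.
        """
        chi2 = self.chi2
        m = chi2.size
        if m == 0:
            return np.nan, np.nan
        n = float(self.table["n"].iloc[0])
        h2 = (chi2.mean() - 1.0) * m / n
        se = chi2.std(ddof=1) / np.sqrt(m) * m / n if m > 1 else np.nan
        return float(h2), float(se)

    @property
    def n_genome_wide(self) -> int:
        return int((self.ok["p"] < GENOME_WIDE_P).sum())

    def sumstats(self) -> pd.DataFrame:
        """PLINK-style summary statistics table."""
        t = self.table
        out = pd.DataFrame(
            {
                "SNP": t["snp"],
                "CHR": t["chrom"],
                "BP": t["pos"],
                "A1": t["alt"],
                "A2": t["ref"],
                "MAF": t["maf"],
                "INFO": t["info"],
                "BETA": t["effect"],
                "SE": t["se"],
                "Z": t["z"],
                "P": t["p"],
                "N": t["n"],
            }
        )
        return out

    def summary(self) -> str:
        h2, h2_se = self.h2_estimate()
        lines = [
            f"Additive {self.model.family} association scan",
            f"  samples: {self.model.nobs}    variants tested: {len(self.table)}",
            f"  converged fits: {len(self.ok)}",
            f"  lambda_GC: {self.lambda_gc:.4f}",
            f"  h2_SNP (constant-LD): {h2:.4f} (se {h2_se:.4f})",
            f"  genome-wide significant (p < {GENOME_WIDE_P:g}): {self.n_genome_wide}",
        ]
        return "\n".join(lines)


def logistic_scan(
    genotypes: GenotypeMatrix, y, covariates=None, **fit_kw
) -> AssociationScanResults:
    """Logistic per-variant scan (see :class:`AssociationScan`)."""
    return AssociationScan(y, genotypes, covariates, family="logistic").fit(**fit_kw)


def linear_scan(
    genotypes: GenotypeMatrix, y, covariates=None, **fit_kw
) -> AssociationScanResults:
    """Linear (OLS) per-variant scan (see :class:`AssociationScan`)."""
    return AssociationScan(y, genotypes, covariates, family="linear").fit(**fit_kw)


# ---------------------------------------------------------------------------
# scan-level diagnostics


def genomic_inflation(p=None, chi2=None) -> float:
    """Genomic-control inflation factor lambda_GC.

    ``median(chi2_1) / 0.45494``; chi-square statistics are recovered from
    p-values through the inverse 1-df chi-square CDF when needed.
    """
    if chi2 is None:
        if p is None:
            raise ValueError("provide p-values or chi-square statistics")
        p = np.asarray(p, dtype=float)
        if p.size == 0:
            raise ValueError("empty input")
        chi2 = stats.chi2.isf(p, df=1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty input")
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


class LDScoreRegression:
    """Single-component LD-score regression for SNP heritability.

    Model: ``E[chi2_j] = intercept + (N * h2 / M) * ell_j`` where ``ell_j``
    is variant j's LD score, ``N`` the GWAS sample size and ``M`` the
    number of variants.  Fit by two-step weighted least squares with
    heteroskedasticity weights ``1 / (2 * (1 + N*h2*ell/M)^2)`` (the
    sampling variance of a non-central chi-square mean), the first step
    being OLS to obtain a provisional slope.
    """

    def __init__(self, chi2, ld_scores, n_samples: int, n_variants: int | None = None):
        self.chi2 = np.asarray(chi2, dtype=float)
        self.ld = np.asarray(ld_scores, dtype=float)
        if self.chi2.shape != self.ld.shape:
            raise ValueError("chi2 and ld_scores must have equal length")
        if np.any(self.ld <= 0):
            raise ValueError("ld_scores must be positive")
        if np.ptp(self.ld) == 0:
            raise ValueError("constant ld_scores: slope is unidentifiable")
        self.n = float(n_samples)
        self.m = float(n_variants if n_variants is not None else self.chi2.size)

    def fit(self):
        import statsmodels.api as sm

        X = sm.add_constant(self.ld)
        ols = sm.OLS(self.chi2, X).fit()
        h2_prov = np.clip(ols.params[1] * self.m / self.n, 0.0, 1.0)
        mean_pred = 1.0 + self.n * h2_prov * self.ld / self.m
        w = 1.0 / (2.0 * mean_pred**2)
        wls = sm.WLS(self.chi2, X, weights=w).fit()
        scale = self.m / self.n
        return LDScoreRegressionResults(
            h2=float(wls.params[1] * scale),
            se=float(wls.bse[1] * scale),
            intercept=float(wls.params[0]),
            intercept_se=float(wls.bse[0]),
            model=self,
        )


class LDScoreRegressionResults:
    def __init__(self, h2, se, intercept, intercept_se, model):
        self.h2 = h2
        self.se = se
        self.intercept = intercept
        self.intercept_se = intercept_se
        self.model = model

    def summary(self) -> str:
        return (
            "LD-score regression\n"
            f"  h2_SNP: {self.h2:.4f} (se {self.se:.4f})\n"
            f"  intercept: {self.intercept:.4f} (se {self.intercept_se:.4f})\n"
            f"  variants: {int(self.model.chi2.size)}  N: {int(self.model.n)}"
        )


def h2_regression(
    chi2, ld_scores, n_samples: int, n_variants: int | None = None
) -> tuple[float, float, float]:
    """Functional wrapper around :class:`LDScoreRegression`.

    Returns ``(h2, se, intercept)``.
    """
    res = LDScoreRegression(chi2, ld_scores, n_samples, n_variants).fit()
    return res.h2, res.se, res.intercept
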