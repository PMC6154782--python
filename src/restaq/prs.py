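"""Polygenic risk scoring and quantile-contrast association tests.

A PRS at discovery threshold ``t`` is the sum of effect-weighted
alt-allele dosages over variants with discovery p < t.  Scores are built
at six standard thresholds (5e-8, 5e-5, 0.01, 0.05, 0.1, 0.5), scored
samples are divided into quantile groups (quartiles by default, falling
back to the number of distinct score values when there are fewer — e.g.
tertiles when a single genome-wide-significant SNP yields three possible
scores), and the top and bottom groups are contrasted in a
covariate-adjusted logistic (binary outcome) or linear (score outcome)
model.  Raw p-values are Benjamini-Hochberg adjusted within the declared
family (default: the six thresholds of one outcome).

Because the discovery scan is of *low* relative amplitude, a higher
score means higher genetic liability to disrupted rest-activity rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix

__all__ = [
    "PRSConfig",
    "compute_prs",
    "quantile_groups",
    "quantile_contrast",
    "fdr_adjust",
    "PRSQuantileModel",
]

DEFAULT_THRESHOLDS = (5e-8, 5e-5, 0.01, 0.05, 0.1, 0.5)


@dataclass
class PRSConfig:
    """Thresholds and quantile settings for the PRS analysis."""

    thresholds: tuple = DEFAULT_THRESHOLDS
    n_quantiles: int = 4
    covariates: tuple = ("age", "sex", "townsend", "array") + tuple(
        f"PC{i}" for i in range(1, 9)
    )

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if any(not (0 < x <= 1) for x in t):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = t
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")


def compute_prs(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    threshold: float,
) -> tuple[np.ndarray, dict]:
    """Per-sample polygenic score at one discovery threshold.

    ``sumstats`` needs columns ``CHR, BP, A1, A2, BETA, P`` (A1 is the
    effect allele).  Variants are matched to the target genotypes on
    (chrom, pos); when the target's alt allele equals A1 the dosage is
    used as is, when ref/alt are swapped the effect-allele dosage is
    ``2 - dosage``, otherwise the variant is skipped.

    Returns ``(scores, report)`` where the report counts used / flipped /
    unmatched variants; a score of all zeros with ``n_used == 0`` is
    flagged ``empty``.
    """
    ss = sumstats.loc[sumstats["P"] < threshold]
    target = {
        (c, p): j
        for j, (c, p) in enumerate(
            zip(genotypes.variants["chrom"], genotypes.variants["pos"])
        )
    }
    ref = genotypes.variants["ref"].to_numpy()
    alt = genotypes.variants["alt"].to_numpy()
    scores = np.zeros(genotypes.n_samples)
    n_used = n_flipped = n_unmatched = 0
    for _, row in ss.iterrows():
        j = target.get((row["CHR"], row["BP"]))
        if j is None:
            n_unmatched += 1
            continue
        beta = float(row["BETA"])
        if not np.isfinite(beta):
            n_unmatched += 1
            continue
        if row["A1"] == alt[j] and row["A2"] == ref[j]:
            scores += beta * genotypes.dosages[:, j]
        elif row["A1"] == ref[j] and row["A2"] == alt[j]:
            scores += beta * (2.0 - genotypes.dosages[:, j])
            n_flipped += 1
        else:
            n_unmatched += 1
            continue
        n_used += 1
    report = {
        "threshold": threshold,
        "n_candidates": int(len(ss)),
        "n_used": n_used,
        "n_flipped": n_flipped,
        "n_unmatched": n_unmatched,
        "empty": n_used == 0,
    }
    return scores, report


def quantile_groups(
    scores: np.ndarray, n_quantiles: int = 4
) -> tuple[np.ndarray, int, bool]:
    """Assign rank-based quantile labels 0..q-1 (0 = bottom).

    Ties are broken by stable input (sample) order, so groups differ in
    size by at most one when scores are distinct.  When there are fewer
    distinct score values than requested quantiles, each distinct value
    becomes its own group (e.g. three genotype-driven score values under a
    quartile request yield tertiles) and the fallback is reported.

    Returns ``(labels, n_groups_used, fallback)``.
    """
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("need >= 2 distinct scores to form quantile groups")
    labels = np.empty(scores.size, dtype=np.int64)
    if distinct.size < n_quantiles:
        labels = np.searchsorted(distinct, scores)
        return labels, int(distinct.size), True
    order = np.argsort(scores, kind="stable")
    for q, chunk in enumerate(np.array_split(order, n_quantiles)):
        labels[chunk] = q
    return labels, int(n_quantiles), False


def quantile_contrast(
    scores: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_quantiles: int = 4,
    binary: bool | None = None,
) -> dict:
    """Top-vs-bottom quantile association of a PRS with an outcome.

    Samples are ranked into ``n_quantiles`` score groups; the model is fit
    on the union of the top and bottom groups with a top-group indicator
    plus covariates — logistic for binary outcomes (reporting an odds
    ratio) and OLS for continuous outcomes (reporting a beta).  NaN
    outcomes are dropped after grouping.

    Returns a result row: estimate, 95% CI, p, group sizes, and whether a
    distinct-value fallback reduced the number of groups.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if scores.size != outcome.size:
        raise ValueError("scores and outcome must have equal length")
    labels, q_used, fallback = quantile_groups(scores, n_quantiles)
    sel = (labels == 0) | (labels == q_used - 1)
    sel &= ~np.isnan(outcome)
    if covariates is not None:
        cov = covariates.to_numpy(float)
        sel &= ~np.isnan(cov).any(axis=1)
    top = (labels == q_used - 1)[sel]
    if top.sum() == 0 or (~top).sum() == 0:
        raise ValueError("empty top or bottom quantile group after filtering")
    y = outcome[sel]
    X = top.astype(float)[:, None]
    if covariates is not None:
        X = np.column_stack([X, covariates.to_numpy(float)[sel]])
    X = sm.add_constant(X, prepend=False)

    if binary is None:
        binary = np.all(np.isin(np.unique(y), [0.0, 1.0]))
    if binary:
        fit = sm.Logit(y, X).fit(disp=0)
        est = float(np.exp(fit.params[0]))
        lo, hi = np.exp(fit.conf_int()[0])
        measure = "OR"
    else:
        fit = sm.OLS(y, X).fit()
        est = float(fit.params[0])
        lo, hi = fit.conf_int()[0]
        measure = "beta"
    return {
        "measure": measure,
        "estimate": est,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(fit.pvalues[0]),
        "n_top": int(top.sum()),
        "n_bottom": int((~top).sum()),
        "n_quantiles_used": q_used,
        "fallback": fallback,
    }


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values within one family.

    Adjusted values are monotone in the raw ranks and never smaller than
    the raw p-values; an empty family returns an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class PRSQuantileModel:
    """PRS threshold x outcome analysis, statsmodels-style.

    Builds scores at every configured threshold from discovery summary
    statistics, forms quantile groups and fits the top-vs-bottom contrast
    for each outcome, applying BH FDR within each outcome's threshold
    family.  ``fit()`` returns a results object whose ``table`` mirrors
    the usual (threshold, outcome, estimate, CI, p, p_fdr) layout.
    """

    def __init__(
        self,
        sumstats: pd.DataFrame,
        genotypes: GenotypeMatrix,
        outcomes: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        config: PRSConfig | None = None,
    ):
        self.sumstats = sumstats
        self.genotypes = genotypes
        self.outcomes = outcomes
        self.covariates = covariates
        self.config = config or PRSConfig()

    def fit(self) -> "PRSQuantileResults":
        rows = []
        score_reports = []
        scores_by_thr = {}
        for thr in self.config.thresholds:
            scores, rep = compute_prs(self.sumstats, self.genotypes, thr)
            score_reports.append(rep)
            scores_by_thr[thr] = scores
        for outcome in self.outcomes.columns:
            y = self.outcomes[outcome].to_numpy(float)
            binary = np.all(np.isin(np.unique(y[~np.isnan(y)]), [0.0, 1.0]))
            fam_rows = []
            for thr in self.config.thresholds:
                scores = scores_by_thr[thr]
                base = {"threshold": thr, "outcome": outcome}
                if np.unique(scores).size < 2:
                    fam_rows.append(
                        {**base, "measure": "OR" if binary else "beta",
                         "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "n_top": 0, "n_bottom": 0,
                         "n_quantiles_used": 0, "fallback": False,
                         "skipped": "degenerate_scores"}
                    )
                    continue
                row = quantile_contrast(
                    scores, y, self.covariates, self.config.n_quantiles, binary
                )
                if binary:
                    row["n_cases"] = int(np.nansum(y == 1.0))
                    row["n_controls"] = int(np.nansum(y == 0.0))
                fam_rows.append({**base, **row, "skipped": ""})
            ps = np.array([r["p"] for r in fam_rows], dtype=float)
            ok = ~np.isnan(ps)
            p_fdr = np.full(ps.shape, np.nan)
            if ok.any():
                p_fdr[ok] = fdr_adjust(ps[ok])
            for r, pf in zip(fam_rows, p_fdr):
                r["p_fdr"] = pf
            rows.extend(fam_rows)
        table = pd.DataFrame(rows)
        return PRSQuantileResults(self, table, pd.DataFrame(score_reports), scores_by_thr)


class PRSQuantileResults:
    def __init__(self, model, table, score_reports, scores):
        self.model = model
        self.table = table
        self.score_reports = score_reports
        self.scores = scores  # threshold -> per-sample score array

    def summary(self) -> str:
        lines = ["PRS quantile-contrast associations (top vs bottom group)"]
        for _, r in self.table.iterrows():
            if r.get("skipped"):
                lines.append(
                    f"  p<{r['threshold']:g}  {r['outcome']}: skipped ({r['skipped']})"
                )
                continue
            lines.append(
                "  p<{thr:g}  {out}: {meas} = {est:.3f} "
                "({lo:.3f}, {hi:.3f})  p = {p:.3g}  p_FDR = {pf:.3g}".format(
                    thr=r["threshold"], out=r["outcome"], meas=r["measure"],
                    est=r["estimate"], lo=r["ci_low"], hi=r["ci_high"],
                    p=r["p"], pf=r["p_fdr"],
                )
            )
        return "\n".join(lines)
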