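"""Case definition and phenotype-table assembly.

Low relative amplitude is a case/control phenotype: participants whose
mean RA lies more than two sample standard deviations below the cohort
mean are cases, everyone else is a control.  The module also assembles
the analysis-ready table joining rhythm metrics, covariates and mood
outcomes, optionally enforcing mutual exclusivity between lifetime
diagnosis labels (a case for one diagnosis is set missing for the
others, limiting comorbidity confounding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["low_ra_cases", "assemble_table", "LIFETIME_OUTCOMES"]

#: mutually exclusive lifetime diagnosis labels
LIFETIME_OUTCOMES = ("MDD", "BD", "GAD")


def low_ra_cases(
    mean_ra: np.ndarray | pd.Series,
    n_sd: float = 2.0,
    strict: bool = True,
) -> tuple[np.ndarray, float]:
    """Label low-RA cases as mean RA below ``mean - n_sd * sd``.

    Uses the sample standard deviation (n-1 denominator).  ``strict``
    keeps a value exactly at the threshold a control ("greater than two
    standard deviations below").  NaN inputs get NaN labels and are
    excluded from the moments.

    Returns
    -------
    (labels, threshold)
        ``labels`` is a float array of 1.0 (case), 0.0 (control) or NaN.
    """
    x = np.asarray(mean_ra, dtype=float)
    ok = ~np.isnan(x)
    vals = x[ok]
    if np.unique(vals).size < 2:
        raise ValueError("phenotype undefined: need >= 2 distinct RA values (sd > 0)")
    threshold = float(vals.mean() - n_sd * vals.std(ddof=1))
    labels = np.full(x.shape, np.nan)
    below = x < threshold if strict else x <= threshold
    labels[ok] = below[ok].astype(float)
    return labels, threshold


def assemble_table(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    exclusivity: bool = True,
    n_sd: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Join metrics, covariates and outcomes into one analysis table.

    Parameters
    ----------
    metrics : DataFrame
        Must contain ``participant_id`` and ``mean_RA``.
    covariates : DataFrame
        ``participant_id`` plus adjustment covariates.
    outcomes : DataFrame, optional
        ``participant_id`` plus outcome labels (binary outcomes as
        0/1/NaN; ``neuroticism`` integer).  ``mood_instability`` values of
        "dont_know"/"prefer_not_to_answer" (or NaN) are coded missing.
    exclusivity : bool
        When True, a case for one lifetime diagnosis becomes NaN for the
        other lifetime diagnoses.

    Returns
    -------
    (table, sidecar)
        The joined table with ``low_RA`` labels, and a provenance dict
        with the threshold and moments used.
    """
    for df, name in ((metrics, "metrics"), (covariates, "covariates")):
        if df["participant_id"].duplicated().any():
            raise ValueError(f"duplicate participant ids in {name} table")
    table = metrics.merge(covariates, on="participant_id", how="inner")
    labels, threshold = low_ra_cases(table["mean_RA"].to_numpy(), n_sd=n_sd)
    table["low_RA"] = labels

    if outcomes is not None and len(outcomes.columns) > 1:
        if outcomes["participant_id"].duplicated().any():
            raise ValueError("duplicate participant ids in outcomes table")
        outcomes = outcomes.copy()
        if "mood_instability" in outcomes:
            mi = outcomes["mood_instability"]
            if mi.dtype == object:
                coding = {"yes": 1.0, "no": 0.0, "dont_know": np.nan,
                          "prefer_not_to_answer": np.nan}
                mi = mi.map(lambda v: coding.get(v, v)).astype(float)
            outcomes["mood_instability"] = mi
        if exclusivity:
            present = [c for c in LIFETIME_OUTCOMES if c in outcomes.columns]
            vals = outcomes[present].to_numpy(float, copy=True)
            case = vals == 1.0
            n_case = case.sum(axis=1)
            for j in range(len(present)):
                # a case for any other diagnosis leaves both the case and
                # control group of this one; comorbid cases (>1 label)
                # cannot be attributed and are missing everywhere
                drop = (n_case >= 1) & ~(case[:, j] & (n_case == 1))
                vals[drop, j] = np.nan
            outcomes[present] = vals
        table = table.merge(outcomes, on="participant_id", how="left")

    ra = table["mean_RA"].dropna()
    sidecar = {
        "low_ra_threshold": threshold,
        "ra_mean": float(ra.mean()),
        "ra_sd": float(ra.std(ddof=1)),
        "n_sd": float(n_sd),
        "n_cases": int(np.nansum(labels == 1.0)),
        "n_controls": int(np.nansum(labels == 0.0)),
        "exclusivity": bool(exclusivity),
    }
    return table, sidecar
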