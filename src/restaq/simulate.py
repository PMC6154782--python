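"""Synthetic cohort generator.

Emulates the data the analysis consumes, with known ground truth:

* seven-day wrist-accelerometer traces at 5-s epochs with a diurnal
  square-wave active/rest structure, multiplicative gamma noise,
  random missingness and device QC flags;
* independent biallelic variants in Hardy-Weinberg equilibrium at chosen
  minor-allele frequencies, with imputation INFO scores;
* covariates matching the cohort protocol (age 37-73, sex, genotyping
  array, 8 genetic principal components, Townsend deprivation index);
* a continuous rest-activity (RA) liability with an additive genetic
  component at a target heritability, and mood outcomes (binary labels
  and a 0-12 neuroticism score) whose liabilities have a controlled
  correlation with the *low-RA* (disruption) liability.

Everything is reproducible from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ActivitySeries, CohortTruth, GenotypeMatrix

__all__ = [
    "ActigraphyParams",
    "gen_actigraphy",
    "gen_genotypes",
    "gen_covariates",
    "make_truth",
    "gen_phenotypes",
]

#: binary outcome labels produced by :func:`gen_phenotypes`
BINARY_OUTCOMES = ("mood_instability", "MDD", "BD", "GAD")

#: default disease/trait prevalences used when a truth object does not
#: override them (mood instability is common; lifetime diagnoses rarer)
DEFAULT_PREVALENCE = {
    "mood_instability": 0.45,
    "MDD": 0.25,
    "BD": 0.012,
    "GAD": 0.07,
}


@dataclass
class ActigraphyParams:
    """Parameters of the diurnal square-wave activity generator.

    The daily profile is ``active_level`` during a contiguous active block
    of ``active_duration_h`` hours starting at ``active_onset_h`` and
    ``rest_level`` otherwise, modulated by multiplicative gamma noise with
    unit mean and coefficient of variation ``noise_cv``.  When
    ``active_duration_h >= 10`` and the rest block spans at least 5 h the
    relative amplitude of the noiseless profile is analytically
    ``(active_level - rest_level) / (active_level + rest_level)``.
    """

    n_days: int = 7
    epoch_s: int = 5
    rest_level: float = 20.0
    active_level: float = 100.0
    active_onset_h: float = 8.0
    active_duration_h: float = 10.0
    noise_cv: float = 0.3
    missing_rate: float = 0.02
    smoothing_half_width_h: float = 0.0
    dst_rate: float = 0.046
    size_flag_rate: float = 0.0003
    calibration_flag_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_days <= 0 or self.epoch_s <= 0:
            raise ValueError("n_days and epoch_s must be positive integers")
        if 86400 % int(self.epoch_s) != 0:
            raise ValueError("epoch_s must divide 86400")
        if not (self.active_level > self.rest_level >= 0):
            raise ValueError("need active_level > rest_level >= 0")
        if not (0 < self.active_duration_h < 24):
            raise ValueError("active_duration_h must lie in (0, 24)")
        if not (0 <= self.active_onset_h < 24):
            raise ValueError("active_onset_h must lie in [0, 24)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def ra_true(self) -> float:
        """Analytic RA of the noiseless profile."""
        return (self.active_level - self.rest_level) / (
            self.active_level + self.rest_level
        )


def _daily_profile(params: ActigraphyParams, rest_level: float) -> np.ndarray:
    """Noiseless one-day level process at epoch resolution."""
    epd = 86400 // int(params.epoch_s)
    t_h = (np.arange(epd) * params.epoch_s) / 3600.0
    in_active = ((t_h - params.active_onset_h) % 24.0) < params.active_duration_h
    level = np.where(in_active, params.active_level, rest_level)
    w = params.smoothing_half_width_h
    if w > 0:
        # moving-average smoothing over +/- w hours, circular in the day
        k = max(1, int(round(2 * w * 3600 / params.epoch_s)))
        kernel = np.ones(k) / k
        level = np.real(
            np.fft.ifft(np.fft.fft(level) * np.fft.fft(kernel, n=epd))
        )
    return level


def gen_actigraphy(
    params: ActigraphyParams,
    n_participants: int,
    ra_true: np.ndarray | None = None,
    start: str = "2015-06-01",
) -> tuple[list[ActivitySeries], CohortTruth]:
    """Simulate epoch-level activity traces for a cohort.

    Parameters
    ----------
    params : ActigraphyParams
        Shared waveform/noise/missingness settings.
    n_participants : int
        Cohort size.
    ra_true : array-like, optional
        Per-participant target relative amplitude in (0, 1).  When given,
        each participant's rest level is set to
        ``active_level * (1 - RA) / (1 + RA)`` so the noiseless profile has
        exactly that RA; otherwise every participant shares
        ``params.rest_level``.
    start : str
        Local midnight at which every recording starts (ISO date).

    Returns
    -------
    (series, truth)
        List of :class:`ActivitySeries` and a :class:`CohortTruth` carrying
        the per-participant analytic RA.
    """
    params.validate()
    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    rng = np.random.default_rng(params.seed)
    if ra_true is not None:
        ra_true = np.asarray(ra_true, dtype=float)
        if ra_true.shape != (n_participants,):
            raise ValueError("ra_true must have one value per participant")
        if np.any((ra_true <= 0) | (ra_true >= 1)):
            raise ValueError("ra_true values must lie strictly in (0, 1)")

    start64 = np.datetime64(start)
    epd = 86400 // int(params.epoch_s)
    n_epochs = epd * params.n_days
    series: list[ActivitySeries] = []
    truths = np.empty(n_participants)
    for i in range(n_participants):
        if ra_true is None:
            rest = params.rest_level
            truths[i] = params.ra_true
        else:
            rest = params.active_level * (1 - ra_true[i]) / (1 + ra_true[i])
            truths[i] = ra_true[i]
        level = np.tile(_daily_profile(params, rest), params.n_days)
        if params.noise_cv > 0:
            cv2 = params.noise_cv**2
            noise = rng.gamma(shape=1.0 / cv2, scale=cv2, size=n_epochs)
            values = level * noise
        else:
            values = level.copy()
        missing = (
            rng.random(n_epochs) < params.missing_rate
            if params.missing_rate > 0
            else np.zeros(n_epochs, dtype=bool)
        )
        flags = {
            "dst_overlap": bool(rng.random() < params.dst_rate),
            "size_unreliable": bool(rng.random() < params.size_flag_rate),
            "calibration_poor": bool(rng.random() < params.calibration_flag_rate),
        }
        series.append(
            ActivitySeries(
                participant_id=f"P{i:06d}",
                start=start64,
                epoch_s=params.epoch_s,
                values=values,
                missing=missing,
                flags=flags,
            )
        )
    truth = CohortTruth(ra_true=truths)
    return series, truth


def gen_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
    info_range: tuple[float, float] = (0.9, 1.0),
) -> GenotypeMatrix:
    """Draw independent biallelic hard genotypes under Hardy-Weinberg.

    Each variant's minor-allele frequency is uniform on ``maf_range`` and
    genotypes are Binomial(2, f) alt-allele counts.  Variants are assigned
    to chromosomes 1-22 with sorted positions and random ref/alt bases, and
    get an imputation INFO score uniform on ``info_range``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_samples < 0 or n_variants < 0:
        raise ValueError("n_samples and n_variants must be non-negative")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    dosages = rng.binomial(2, mafs[None, :], size=(n_samples, n_variants)).astype(
        float
    )
    chrom = np.sort(rng.integers(1, 23, size=n_variants))
    pos = np.empty(n_variants, dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        pos[m] = np.sort(rng.integers(1, 50_000_000, size=m.sum()))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_variants)]
    alt_off = rng.integers(1, 4, size=n_variants)
    alt = bases[(np.searchsorted(bases, ref) + alt_off) % 4]
    variants = pd.DataFrame(
        {
            "snp": [f"rs{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "info": rng.uniform(*info_range, size=n_variants),
            "maf_true": mafs,
        }
    )
    sample_ids = np.array([f"S{i:06d}" for i in range(n_samples)], dtype=object)
    return GenotypeMatrix(sample_ids, variants, dosages)


def gen_covariates(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Simulate the adjustment covariates used throughout the analysis.

    age ~ U(37, 73) years (the recruitment age range), sex ~ Bernoulli(0.5),
    genotyping array ~ Bernoulli(0.1) (the approximate fraction typed on the
    secondary array), PC1-PC8 standard normal, Townsend index standard
    normal.
    """
    rng = np.random.default_rng(seed)
    cov = {
        "age": rng.uniform(37, 73, size=n_samples),
        "sex": rng.integers(0, 2, size=n_samples).astype(float),
        "array": (rng.random(n_samples) < 0.1).astype(float),
    }
    for k in range(1, 9):
        cov[f"PC{k}"] = rng.standard_normal(n_samples)
    cov["townsend"] = rng.standard_normal(n_samples)
    return pd.DataFrame(cov, index=pd.RangeIndex(n_samples))


def make_truth(
    n_variants: int,
    n_causal: int,
    h2: float,
    seed: int = 0,
    covar_coefs: dict | None = None,
    outcome_corr: dict | None = None,
    outcome_prevalence: dict | None = None,
) -> CohortTruth:
    """Draw ground-truth effect sizes and outcome-overlap settings.

    ``n_causal`` variants receive normal effects on the standardised-dosage
    scale, normalised so the genetic values have unit variance before the
    heritability scaling in :func:`gen_phenotypes`.  ``outcome_corr`` maps
    outcome names to the correlation between that outcome's liability and
    the low-RA (disruption) liability.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    if n_causal > n_variants:
        raise ValueError("n_causal cannot exceed n_variants")
    rng = np.random.default_rng(seed)
    effects = np.zeros(n_variants)
    if n_causal > 0:
        idx = rng.choice(n_variants, size=n_causal, replace=False)
        b = rng.standard_normal(n_causal)
        b /= np.sqrt((b**2).sum()) if np.any(b) else 1.0
        effects[idx] = b
    corr = dict(outcome_corr or {})
    for name in BINARY_OUTCOMES + ("neuroticism",):
        corr.setdefault(name, 0.0)
    prev = dict(DEFAULT_PREVALENCE)
    prev.update(outcome_prevalence or {})
    return CohortTruth(
        effects=effects,
        h2=h2,
        covar_coefs=dict(covar_coefs or {}),
        outcome_corr=corr,
        outcome_prevalence=prev,
    )


def _standardise_dosages(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages
    f = d.mean(axis=0) / 2.0
    sd = np.sqrt(2 * f * (1 - f))
    sd[sd == 0] = 1.0
    return (d - 2 * f) / sd


def gen_phenotypes(
    genotypes: GenotypeMatrix,
    truth: CohortTruth,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    ra_mean: float = 0.87,
    ra_sd: float = 0.06,
) -> pd.DataFrame:
    """Simulate RA liabilities and mood outcomes from genotypes.

    The continuous rest-activity liability is ``G + c'X + e`` where ``G``
    is the additive genetic value from ``truth.effects`` (standardised
    dosages), ``c`` the covariate coefficients and ``e`` Gaussian noise
    scaled so the realised heritability of the covariate-free part equals
    ``truth.h2``.  The *disruption* (low-RA) liability is the negated,
    standardised covariate-free liability; each outcome's liability is
    ``rho * disruption + sqrt(1-rho^2) * eps`` with ``rho`` from
    ``truth.outcome_corr``, thresholded at its empirical prevalence
    quantile.  The neuroticism score is an integer 0-12 derived from its
    liability.  ``mean_ra`` maps the liability affinely onto the observed
    RA scale (mean ``ra_mean``, SD ``ra_sd``), clipped to (0, 1).

    Returns a DataFrame indexed like ``genotypes.sample_ids`` with columns
    ``ra_liability``, ``mean_ra``, the binary outcomes (0/1 floats) and
    ``neuroticism``; ``truth`` is updated in place with the realised
    genetic values and liabilities.
    """
    truth.validate(genotypes.n_variants)
    n = genotypes.n_samples
    if covariates is not None and len(covariates) != n:
        raise ValueError("covariate table length does not match sample count")
    rng = np.random.default_rng(seed)

    if genotypes.n_variants and np.any(truth.effects):
        z = _standardise_dosages(genotypes)
        g_raw = z @ truth.effects
    else:
        g_raw = np.zeros(n)

    h2 = float(truth.h2)
    sd_g = g_raw.std()
    if h2 > 0 and sd_g > 0:
        g = np.sqrt(h2) * g_raw / sd_g
        e = rng.standard_normal(n)
        e = np.sqrt(1 - h2) * (e - e.mean()) / e.std() if h2 < 1 else np.zeros(n)
    else:
        g = np.zeros(n)
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std()
    liab0 = g + e  # covariate-free liability, ~N(0,1) realised

    cov_term = np.zeros(n)
    if covariates is not None and truth.covar_coefs:
        for name, coef in truth.covar_coefs.items():
            cov_term = cov_term + float(coef) * covariates[name].to_numpy(float)
    ra_liability = liab0 + cov_term
    disruption = -(liab0 - liab0.mean()) / liab0.std()

    out = pd.DataFrame(index=pd.RangeIndex(n))
    out["participant_id"] = genotypes.sample_ids
    out["ra_liability"] = ra_liability
    out["mean_ra"] = np.clip(
        ra_mean + ra_sd * (ra_liability - ra_liability.mean()) / ra_liability.std(),
        1e-3,
        1 - 1e-3,
    )
    for name in BINARY_OUTCOMES:
        rho = float(truth.outcome_corr.get(name, 0.0))
        prev = float(truth.outcome_prevalence.get(name, 0.1))
        eps = rng.standard_normal(n)
        liab = rho * disruption + np.sqrt(max(0.0, 1 - rho**2)) * eps
        cut = np.quantile(liab, 1 - prev)
        out[name] = (liab > cut).astype(float)
    rho_n = float(truth.outcome_corr.get("neuroticism", 0.0))
    eps = rng.standard_normal(n)
    liab_n = rho_n * disruption + np.sqrt(max(0.0, 1 - rho_n**2)) * eps
    out["neuroticism"] = np.clip(np.round(4.0 + 3.0 * liab_n), 0, 12).astype(int)

    truth.genetic_value = g
    truth.ra_liability = ra_liability
    truth.disruption_liability = disruption
    return out
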