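"""Core in-memory containers shared across the pipeline.

The containers are deliberately thin: an :class:`ActivitySeries` is one
participant's epoch-level activity trace with a missingness mask and
device-level QC flags; a :class:`GenotypeMatrix` is a samples x variants
dosage matrix with a variant-metadata table. Statistical results live in
the Results classes of :mod:`restaq.gwas` and :mod:`restaq.prs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "QCReport",
    "RhythmMetrics",
    "GenotypeMatrix",
    "CohortTruth",
]

#: device / wear-time QC flag names, in exclusion-precedence order after the
#: wear-time rules (size before calibration before DST)
FLAG_NAMES = ("size_unreliable", "calibration_poor", "dst_overlap")


@dataclass
class ActivitySeries:
    """Epoch-level activity for one participant.

    Parameters
    ----------
    participant_id : str
        Cohort-unique identifier.
    start : numpy.datetime64
        Timestamp of the first epoch; must fall on a local midnight so that
        day boundaries are midnight-to-midnight.
    epoch_s : int
        Epoch length in seconds (5 s in the reference protocol).
    values : ndarray of float
        Mean activity intensity per epoch (arbitrary non-negative units).
    missing : ndarray of bool
        True where no valid data were recorded for the epoch.
    flags : dict
        Device QC flags: ``calibration_poor``, ``size_unreliable``,
        ``dst_overlap`` (daylight-saving clock change during wear).
    """

    participant_id: str
    start: np.datetime64
    epoch_s: int
    values: np.ndarray
    missing: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have equal length")
        self.start = np.datetime64(self.start)
        if self.start != self.start.astype("datetime64[D]").astype(self.start.dtype):
            raise ValueError("series must start at a local midnight")
        ok = self.values[~self.missing]
        if ok.size and np.nanmin(ok) < 0:
            raise ValueError("activity values must be non-negative where not missing")
        for name in FLAG_NAMES:
            self.flags.setdefault(name, False)

    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def epochs_per_day(self) -> int:
        return 86400 // int(self.epoch_s)

    @property
    def wear_hours(self) -> float:
        """Total non-missing wear time, in hours."""
        return float((~self.missing).sum()) * self.epoch_s / 3600.0

    def hour_of_day(self) -> np.ndarray:
        """Hour-of-day bin (0-23) of each epoch."""
        idx = np.arange(self.n_epochs, dtype=np.int64)
        return (idx * self.epoch_s // 3600) % 24


@dataclass
class QCReport:
    """Cohort-level accounting of wear-time / device exclusions.

    Counts use first-matching-reason attribution so that
    ``n_retained + sum(exclusion counts) == n_input`` always holds.
    """

    n_input: int = 0
    n_excluded_short: int = 0
    n_excluded_hour_coverage: int = 0
    n_excluded_size: int = 0
    n_excluded_calibration: int = 0
    n_excluded_dst: int = 0
    n_retained: int = 0
    reasons: dict = field(default_factory=dict)  # participant_id -> reason str

    @property
    def n_excluded(self) -> int:
        return (
            self.n_excluded_short
            + self.n_excluded_hour_coverage
            + self.n_excluded_size
            + self.n_excluded_calibration
            + self.n_excluded_dst
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("excluded_short", self.n_excluded_short),
            ("excluded_hour_coverage", self.n_excluded_hour_coverage),
            ("excluded_size", self.n_excluded_size),
            ("excluded_calibration", self.n_excluded_calibration),
            ("excluded_dst", self.n_excluded_dst),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["category", "n"])


@dataclass
class RhythmMetrics:
    """Non-parametric rest-activity metrics for one participant.

    ``per_day`` has one row per midnight-to-midnight day with columns
    ``day``, ``M10``, ``L5``, ``RA``, ``M10_onset_h``, ``L5_onset_h``,
    ``valid``; participant-level summaries are the mean RA over valid days
    plus interdaily stability (IS), intradaily variability (IV) and the
    24-h cosinor amplitude.
    """

    participant_id: str
    per_day: pd.DataFrame
    mean_RA: float
    IS: float
    IV: float
    cosinor_amplitude: float
    cosinor_mesor: float
    cosinor_acrophase_h: float
    n_valid_days: int

    def summary_row(self) -> dict:
        valid = self.per_day[self.per_day["valid"]]
        return {
            "participant_id": self.participant_id,
            "mean_RA": self.mean_RA,
            "M10": float(valid["M10"].mean()) if len(valid) else np.nan,
            "L5": float(valid["L5"].mean()) if len(valid) else np.nan,
            "IS": self.IS,
            "IV": self.IV,
            "cosinor_amplitude": self.cosinor_amplitude,
            "n_valid_days": self.n_valid_days,
        }


class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Dosages are alt-allele doses in [0, 2] (hard genotypes or imputed
    expectations). ``variants`` is a DataFrame with columns
    ``snp``, ``chrom``, ``pos`` (1-based), ``ref``, ``alt``, ``info``.
    """

    REQUIRED_COLS = ("snp", "chrom", "pos", "ref", "alt", "info")

    def __init__(self, sample_ids, variants: pd.DataFrame, dosages: np.ndarray):
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        self.variants = variants.reset_index(drop=True)
        self.dosages = np.asarray(dosages, dtype=float)
        for col in self.REQUIRED_COLS:
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing required column {col!r}")
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                "dosage shape %s does not match %d samples x %d variants"
                % (self.dosages.shape, len(self.sample_ids), len(self.variants))
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant (mean dosage / 2)."""
        if self.n_variants == 0:
            return np.empty(0)
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.iloc[index],
            self.dosages[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.sample_ids[index], self.variants, self.dosages[index, :]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_variants} variants>"


@dataclass
class CohortTruth:
    """Ground truth carried alongside a simulated cohort.

    Used by parameter-recovery tests: the realised per-variant effects on the
    rest-activity liability, the target heritability, covariate coefficients,
    each participant's true relative amplitude, and the correlations between
    outcome liabilities and the low-RA (disruption) liability.
    """

    effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    h2: float = 0.0
    covar_coefs: dict = field(default_factory=dict)
    ra_true: np.ndarray | None = None
    outcome_corr: dict = field(default_factory=dict)
    outcome_prevalence: dict = field(default_factory=dict)
    genetic_value: np.ndarray | None = None
    ra_liability: np.ndarray | None = None
    disruption_liability: np.ndarray | None = None

    def validate(self, n_variants: int) -> None:
        if not 0.0 <= float(self.h2) <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.effects.size != n_variants:
            raise ValueError(
                f"effect vector length {self.effects.size} != variant count {n_variants}"
            )

    def to_json_dict(self) -> dict:
        return {
            "h2": float(self.h2),
            "effects": np.asarray(self.effects, dtype=float).tolist(),
            "covar_coefs": {k: float(v) for k, v in self.covar_coefs.items()},
            "ra_true": None
            if self.ra_true is None
            else np.asarray(self.ra_true, dtype=float).tolist(),
            "outcome_corr": {k: float(v) for k, v in self.outcome_corr.items()},
            "outcome_prevalence": {
                k: float(v) for k, v in self.outcome_prevalence.items()
            },
        }
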