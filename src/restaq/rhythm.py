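"""Non-parametric rest-activity rhythm metrics.

The primary statistic is relative amplitude (RA): for each
midnight-to-midnight day, M10 is the mean activity over the most active
continuous 10-h window and L5 the mean over the least active continuous
5-h window, and ``RA = (M10 - L5) / (M10 + L5)``.  RA is scale-free and
lies in [0, 1]; a participant's RA is the mean over their valid recorded
days.  Interdaily stability (IS), intradaily variability (IV) and the
24-h cosinor amplitude are computed as comparators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ActivitySeries, RhythmMetrics

__all__ = [
    "m10_l5",
    "relative_amplitude",
    "participant_metrics",
    "cohort_metrics",
    "interdaily_stability",
    "intradaily_variability",
    "cosinor_fit",
]

logger = logging.getLogger(__name__)

M10_HOURS = 10
L5_HOURS = 5


def _bin_day(values, missing, epoch_s, bin_min):
    """Aggregate one day of epochs into bins of ``bin_min`` minutes.

    Returns (bin_means, bin_valid); a bin's mean is over its non-missing
    epochs and a bin is invalid when it has none.
    """
    bin_s = bin_min * 60
    if bin_s % epoch_s != 0 and epoch_s % bin_s != 0:
        raise ValueError("bin_min must be commensurate with epoch_s")
    if epoch_s > bin_s:
        raise ValueError("bin_min must be at least one epoch long")
    per_bin = bin_s // epoch_s
    n_bins = values.size // per_bin
    v = np.where(missing, 0.0, values)[: n_bins * per_bin].reshape(n_bins, per_bin)
    ok = (~missing)[: n_bins * per_bin].reshape(n_bins, per_bin)
    counts = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, v.sum(axis=1) / np.maximum(counts, 1), np.nan)
    return means, counts > 0


def _window_means(bin_means, bin_valid, width_bins):
    """Mean over non-missing bins for every window start (no wraparound).

    Sums each window directly (not via prefix-sum differences) so the
    result is bitwise identical to enumerating the windows one by one.
    """
    n = bin_means.size
    if width_bins > n:
        return np.empty(0)
    vals = np.where(bin_valid, bin_means, 0.0)
    windows = np.lib.stride_tricks.sliding_window_view(vals, width_bins)
    counts = np.lib.stride_tricks.sliding_window_view(
        bin_valid.astype(np.int64), width_bins
    ).sum(axis=-1)
    sums = windows.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def m10_l5(
    values: np.ndarray,
    missing: np.ndarray | None = None,
    epoch_s: int = 5,
    bin_min: int = 1,
) -> tuple[float, float, float, float]:
    """M10 and L5 of one midnight-to-midnight day.

    Parameters
    ----------
    values, missing : arrays covering exactly 24 h at uniform epochs.
    bin_min : int
        Window-search resolution in minutes; windows slide in steps of one
        bin and do not wrap across midnight.

    Returns
    -------
    (M10, L5, m10_onset_h, l5_onset_h)
        Window means and the hour-of-day at which each winning window
        starts; the earliest window wins ties.  NaN metrics when no window
        contains data.
    """
    values = np.asarray(values, dtype=float)
    missing = (
        np.zeros(values.shape, dtype=bool)
        if missing is None
        else np.asarray(missing, dtype=bool)
    )
    if values.size * epoch_s != 86400:
        raise ValueError("day vector must cover exactly 24 h")
    if (M10_HOURS * 60) % bin_min or (L5_HOURS * 60) % bin_min:
        raise ValueError("bin_min must divide both window lengths")
    means, valid = _bin_day(values, missing, epoch_s, bin_min)
    w10 = M10_HOURS * 60 // bin_min
    w5 = L5_HOURS * 60 // bin_min
    m10_means = _window_means(means, valid, w10)
    l5_means = _window_means(means, valid, w5)
    if m10_means.size == 0 or np.all(np.isnan(m10_means)):
        return np.nan, np.nan, np.nan, np.nan
    i10 = int(np.nanargmax(m10_means))
    i5 = int(np.nanargmin(l5_means))
    return (
        float(m10_means[i10]),
        float(l5_means[i5]),
        (i10 * bin_min) / 60.0,
        (i5 * bin_min) / 60.0,
    )


def relative_amplitude(m10: float, l5: float) -> float:
    """RA = (M10 - L5) / (M10 + L5); 0 when both are 0.

    Raises if ``l5 > m10`` (violates the definition of the extremal
    windows) beyond floating tolerance.
    """
    if np.isnan(m10) or np.isnan(l5):
        return np.nan
    if l5 > m10 * (1 + 1e-12) + 1e-12:
        raise ValueError(f"L5 ({l5}) exceeds M10 ({m10})")
    if m10 <= 0:
        return 0.0
    l5 = min(l5, m10)
    return (m10 - l5) / (m10 + l5)


def interdaily_stability(hourly: np.ndarray, valid: np.ndarray) -> float:
    """IS: variance of the mean 24-h profile over total variance.

    1 for a perfectly repeating daily profile, ~0 for Gaussian noise.
    Constant signals (zero total variance) return 1 by convention.
    """
    x = hourly[valid]
    if x.size < 24:
        return np.nan
    grand = x.mean()
    denom = ((x - grand) ** 2).mean()
    hod = (np.arange(hourly.size) % 24)[valid]
    num = 0.0
    for h in range(24):
        m = hod == h
        if m.any():
            num += m.sum() * (x[m].mean() - grand) ** 2
    num /= x.size
    if denom <= 0:
        return 1.0
    return float(num / denom)


def intradaily_variability(hourly: np.ndarray, valid: np.ndarray) -> float:
    """IV: mean squared successive difference over variance of hourly means.

    0 for a smooth/constant signal, ~2 for white noise.
    """
    x = np.where(valid, hourly, np.nan)
    pairs = valid[1:] & valid[:-1]
    xv = hourly[valid]
    if xv.size < 2 or pairs.sum() < 1:
        return np.nan
    var = ((xv - xv.mean()) ** 2).sum() / (xv.size - 1)
    if var <= 0:
        return 0.0
    msd = ((x[1:] - x[:-1])[pairs] ** 2).sum() / pairs.sum()
    return float(msd / var)


def cosinor_fit(
    values: np.ndarray,
    missing: np.ndarray,
    epoch_s: int,
    period_h: float = 24.0,
) -> tuple[float, float, float]:
    """Least-squares fit of ``mesor + A*cos(2*pi*(t - phi)/period)``.

    Returns (amplitude, mesor, acrophase_h).
    """
    t_h = np.arange(values.size) * (epoch_s / 3600.0)
    ok = ~missing
    if ok.sum() < 3:
        return np.nan, np.nan, np.nan
    theta = 2 * np.pi * t_h[ok] / period_h
    X = np.column_stack([np.ones(ok.sum()), np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(X, values[ok], rcond=None)
    mesor, a, b = coef
    amplitude = float(np.hypot(a, b))
    acrophase = float((np.arctan2(b, a) * period_h / (2 * np.pi)) % period_h)
    return amplitude, float(mesor), acrophase


def participant_metrics(
    series: ActivitySeries,
    bin_min: int = 1,
    min_day_coverage: float = 0.8,
) -> RhythmMetrics:
    """Per-day M10/L5/RA and participant-level summaries for one series.

    A day enters the RA mean only when at least ``min_day_coverage`` of its
    epochs are non-missing and both extremal windows are computable.
    ``mean_RA`` is NaN when no day is valid (the caller decides whether to
    drop the participant).
    """
    epd = series.epochs_per_day
    n_days = series.n_epochs // epd
    rows = []
    for d in range(n_days):
        sl = slice(d * epd, (d + 1) * epd)
        v, m = series.values[sl], series.missing[sl]
        coverage = 1.0 - m.mean()
        if coverage >= min_day_coverage:
            M10, L5, on10, on5 = m10_l5(v, m, series.epoch_s, bin_min)
            valid = not np.isnan(M10)
        else:
            M10 = L5 = on10 = on5 = np.nan
            valid = False
        ra = relative_amplitude(M10, L5) if valid else np.nan
        rows.append(
            {
                "day": d,
                "M10": M10,
                "L5": L5,
                "RA": ra,
                "M10_onset_h": on10,
                "L5_onset_h": on5,
                "coverage": coverage,
                "valid": valid,
            }
        )
    per_day = pd.DataFrame(rows)
    valid_ra = per_day.loc[per_day["valid"], "RA"]
    mean_ra = float(valid_ra.mean()) if len(valid_ra) else np.nan

    hourly, hvalid = _hourly_means(series)
    amplitude, mesor, acro = cosinor_fit(
        series.values, series.missing, series.epoch_s
    )
    return RhythmMetrics(
        participant_id=series.participant_id,
        per_day=per_day,
        mean_RA=mean_ra,
        IS=interdaily_stability(hourly, hvalid),
        IV=intradaily_variability(hourly, hvalid),
        cosinor_amplitude=amplitude,
        cosinor_mesor=mesor,
        cosinor_acrophase_h=acro,
        n_valid_days=int(per_day["valid"].sum()),
    )


def _hourly_means(series: ActivitySeries) -> tuple[np.ndarray, np.ndarray]:
    """Chronological hourly means over the recording (NaN-free mask)."""
    per_hour = 3600 // series.epoch_s
    n_hours = series.n_epochs // per_hour
    v = np.where(series.missing, 0.0, series.values)[: n_hours * per_hour]
    ok = (~series.missing)[: n_hours * per_hour]
    v = v.reshape(n_hours, per_hour)
    ok = ok.reshape(n_hours, per_hour)
    counts = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, v.sum(axis=1) / np.maximum(counts, 1), np.nan)
    return means, counts > 0


def cohort_metrics(
    cohort: list[ActivitySeries],
    bin_min: int = 1,
    min_day_coverage: float = 0.8,
) -> pd.DataFrame:
    """Participant-level metrics table; drops participants with no valid day."""
    rows = []
    for s in cohort:
        m = participant_metrics(s, bin_min=bin_min, min_day_coverage=min_day_coverage)
        if m.n_valid_days == 0 or np.isnan(m.mean_RA):
            logger.warning(
                "participant %s dropped: no valid 24-h day", s.participant_id
            )
            continue
        rows.append(m.summary_row())
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "mean_RA",
            "M10",
            "L5",
            "IS",
            "IV",
            "cosinor_amplitude",
            "n_valid_days",
        ],
    )
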