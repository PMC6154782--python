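"""Raw-sample epoching and participant-level accelerometry QC.

Raw intensity streams are low-pass filtered (4th-order zero-phase
Butterworth, 20 Hz cutoff by default, removing machine noise above the
band of human movement), aggregated into fixed epochs, and recording gaps
longer than one second are coded as missing.  Participant-level exclusions
then drop recordings with under 72 h of wear, recordings that never cover
some hour of the 24-h cycle, and device-flagged recordings (unreliable
size, poor calibration, wear overlapping a daylight-saving clock change).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import ActivitySeries, QCReport

__all__ = ["butter_lowpass", "epoch_from_raw", "apply_exclusions"]

#: order of exclusion-reason attribution; first matching reason wins
EXCLUSION_ORDER = ("short", "hour_coverage", "size", "calibration", "dst")


def butter_lowpass(
    values: np.ndarray, fs: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter of a uniform signal.

    Applied forward and backward (``filtfilt``), so the effective magnitude
    response is the squared Butterworth response and the phase is zero.
    """
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    return signal.filtfilt(b, a, np.asarray(values, dtype=float))


def epoch_from_raw(
    timestamps: np.ndarray,
    values: np.ndarray,
    epoch_s: int = 5,
    target_rate: float = 100.0,
    filter_cutoff: float | None = 20.0,
    filter_order: int = 4,
    gap_s: float = 1.0,
    participant_id: str = "P0",
    start: str | np.datetime64 = "2015-06-01",
) -> ActivitySeries:
    """Aggregate a raw high-rate intensity stream into fixed epochs.

    Parameters
    ----------
    timestamps : array of float
        Sample times in seconds since the recording's local midnight,
        strictly increasing.
    values : array of float
        Raw activity intensity per sample.
    epoch_s : int
        Epoch length in seconds; epochs are half-open ``[t, t+epoch_s)``
        intervals indexed by start time from second 0.
    target_rate : float
        Uniform rate (Hz) the stream is resampled to (linear
        interpolation) before filtering.
    filter_cutoff : float or None
        Butterworth low-pass cutoff in Hz; ``None`` disables filtering.
    gap_s : float
        Stretches between consecutive samples longer than this are coded
        missing; every epoch whose interval intersects a gap is masked.
        Filter undershoot is clipped to zero (activity intensity is
        non-negative).

    Returns
    -------
    ActivitySeries
        Epoch means of the filtered stream covering whole days from
        ``start``'s midnight through the last sampled epoch.
    """
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != x.shape:
        raise ValueError("timestamps and values must have equal length")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")

    n_epochs = int(np.ceil((t[-1] + 1e-12) / epoch_s))
    n_epochs = max(n_epochs, 1)

    # already-epoch-level input (spacing == epoch_s on the epoch grid)
    # passes through unchanged: the low-pass targets machine noise far
    # above the epoch band, so epoching is idempotent
    if (
        t.size > 1
        and np.allclose(np.diff(t), epoch_s)
        and abs(t[0] % epoch_s) < 1e-9
    ):
        n_epochs = t.size
        values_out = x.copy()
        missing = ~np.isfinite(values_out)
        values_out[missing] = 0.0
        epd = 86400 // int(epoch_s)
        total = int(np.ceil(n_epochs / epd)) * epd
        if total > n_epochs:
            pad = total - n_epochs
            values_out = np.concatenate([values_out, np.zeros(pad)])
            missing = np.concatenate([missing, np.ones(pad, dtype=bool)])
        return ActivitySeries(
            participant_id=participant_id,
            start=np.datetime64(start),
            epoch_s=int(epoch_s),
            values=values_out,
            missing=missing,
        )

    # uniform grid for filtering
    dt = 1.0 / target_rate
    grid = np.arange(0.0, n_epochs * epoch_s, dt)
    on_grid = np.interp(grid, t, x, left=x[0], right=x[-1])
    filtered = (
        butter_lowpass(on_grid, fs=target_rate, cutoff=filter_cutoff, order=filter_order)
        if filter_cutoff is not None
        else on_grid
    )
    filtered = np.maximum(filtered, 0.0)

    epoch_idx = np.minimum((grid / epoch_s).astype(np.int64), n_epochs - 1)
    sums = np.bincount(epoch_idx, weights=filtered, minlength=n_epochs)
    counts = np.bincount(epoch_idx, minlength=n_epochs)
    with np.errstate(invalid="ignore"):
        epoch_values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    missing = counts == 0
    # recording gaps: mark every epoch whose half-open interval intersects
    # an inter-sample stretch longer than gap_s, plus lead-in / tail-out
    gaps = []
    if t[0] > gap_s:
        gaps.append((0.0, t[0]))
    if t.size > 1:
        d = np.diff(t)
        for i in np.flatnonzero(d > gap_s):
            gaps.append((t[i], t[i + 1]))
    starts = np.arange(n_epochs) * float(epoch_s)
    ends = starts + epoch_s
    for g0, g1 in gaps:
        missing |= (starts < g1) & (ends > g0)
    epoch_values = np.where(missing, 0.0, epoch_values)

    # pad to whole days so day boundaries stay midnight-to-midnight
    epd = 86400 // int(epoch_s)
    total = int(np.ceil(n_epochs / epd)) * epd
    if total > n_epochs:
        pad = total - n_epochs
        epoch_values = np.concatenate([epoch_values, np.zeros(pad)])
        missing = np.concatenate([missing, np.ones(pad, dtype=bool)])

    return ActivitySeries(
        participant_id=participant_id,
        start=np.datetime64(start),
        epoch_s=int(epoch_s),
        values=epoch_values,
        missing=missing,
    )


def _exclusion_reason(
    series: ActivitySeries, min_wear_h: float
) -> str | None:
    """First matching exclusion reason, or None if retained."""
    if series.wear_hours < min_wear_h:
        return "short"
    hours = series.hour_of_day()
    covered = np.zeros(24, dtype=bool)
    covered[np.unique(hours[~series.missing])] = True
    if not covered.all():
        return "hour_coverage"
    if series.flags.get("size_unreliable", False):
        return "size"
    if series.flags.get("calibration_poor", False):
        return "calibration"
    if series.flags.get("dst_overlap", False):
        return "dst"
    return None


def apply_exclusions(
    cohort: list[ActivitySeries], min_wear_h: float = 72.0
) -> tuple[list[ActivitySeries], QCReport]:
    """Apply participant-level accelerometry exclusions.

    A recording is excluded when its non-missing wear time is below
    ``min_wear_h`` hours, when some hour-of-day bin (0-23) has no
    non-missing epoch anywhere in the recording, or when any device flag
    is set.  One reason is attributed per participant, in the fixed order
    short, hour-coverage, size, calibration, DST, so the report's counts
    partition the input.
    """
    report = QCReport(n_input=len(cohort))
    retained: list[ActivitySeries] = []
    for s in cohort:
        reason = _exclusion_reason(s, min_wear_h)
        if reason is None:
            retained.append(s)
            report.n_retained += 1
        else:
            report.reasons[s.participant_id] = reason
            setattr(
                report,
                f"n_excluded_{reason}",
                getattr(report, f"n_excluded_{reason}") + 1,
            )
    return retained, report
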