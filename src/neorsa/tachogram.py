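"""Tachogram cleaning, even resampling, and the active-sleep rule.

The cleaning rule flags implausible R-R intervals (outside a generous
neonatal envelope of 200-750 ms, i.e. 80-300 bpm) and local outliers
(deviation from the centered 11-interval running median beyond a fraction of
that median), then repairs them by linear interpolation over beat time; an
epoch with more than 5% flagged intervals is rejected outright rather than
repaired.

Heart-rate variability in beats per minute is defined here as the range
(max - min) of the 3-beat-median-smoothed instantaneous heart rate — the
reading of a "< 10 beats per minute" criterion consistent with a bedside
monitor. The definition is isolated in :func:`hrv_bpm_range` so it can be
swapped without touching the sleep-state rule.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .records import (
    ObservationRecord,
    PATTERN_IRREGULAR_SHALLOW,
    ResampledSeries,
    SleepStateResult,
    Tachogram,
)


class EpochRejectionError(RuntimeError):
    """An epoch failed a quality gate and must be excluded from analysis."""

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


def clean_rr(
    t: Tachogram,
    bounds=(200.0, 750.0),
    dev_frac: float = 0.20,
    max_flag_frac: float = 0.05,
) -> Tachogram:
    """Flag and repair artifactual R-R intervals.

    Raises :class:`EpochRejectionError` when more than ``max_flag_frac`` of
    the intervals are flagged. Idempotent on its own output.
    """
    if len(t) < 10:
        raise ValueError("need at least 10 intervals to clean a tachogram")
    rr = t.rr_ms
    med = median_filter(rr, size=11, mode="nearest")
    flags = (rr < bounds[0]) | (rr > bounds[1]) | (np.abs(rr - med) > dev_frac * med)

    if flags.mean() > max_flag_frac:
        raise EpochRejectionError(
            f"{flags.mean():.1%} of R-R intervals flagged (> {max_flag_frac:.0%})",
            stage="clean_rr",
        )
    repaired = rr.copy()
    if flags.any():
        repaired[flags] = np.interp(
            t.beat_times[flags], t.beat_times[~flags], rr[~flags]
        )
    return Tachogram(
        beat_times=t.beat_times.copy(),
        rr_ms=repaired,
        artifact_flags=flags,
        subject_id=t.subject_id,
        epoch_label=t.epoch_label,
    )


def resample_tachogram(t: Tachogram, rate: float = 4.0) -> Tachogram:
    """Cubic interpolation of the R-R series onto a uniform grid.

    The grid has step exactly ``1/rate`` and is restricted to the interior
    of the beat-time span. Cubic (not linear) interpolation avoids spurious
    high-frequency power from piecewise-linear kinks inside the analysis
    band.
    """
    if len(t) < 4:
        raise ValueError("need at least 4 intervals for cubic resampling")
    if t.span < 10.0:
        raise EpochRejectionError(
            f"tachogram spans only {t.span:.1f} s (< 10 s)", stage="resample"
        )
    k0 = int(np.ceil(t.beat_times[0] * rate - 1e-9))
    k1 = int(np.floor(t.beat_times[-1] * rate + 1e-9))
    grid = np.arange(k0, k1 + 1) / rate
    values = CubicSpline(t.beat_times, t.rr_ms)(grid)
    return Tachogram(
        beat_times=t.beat_times.copy(),
        rr_ms=t.rr_ms.copy(),
        artifact_flags=None if t.artifact_flags is None else t.artifact_flags.copy(),
        resampled=ResampledSeries(
            rate=rate, values=values, start=grid[0], end=grid[-1]
        ),
        subject_id=t.subject_id,
        epoch_label=t.epoch_label,
    )


def hrv_bpm_range(t: Tachogram, window: Optional[float] = None) -> float:
    """Range of median-smoothed instantaneous heart rate, in bpm.

    Instantaneous HR is 60000/rr per interval, smoothed with a centered
    3-beat running median (first and last beats kept as-is); the result is
    max - min over ``window`` seconds from the start of the tachogram (whole
    record when ``window`` is None).
    """
    rr = t.rr_ms
    times = t.beat_times
    if window is not None:
        if window > t.span:
            raise ValueError("window longer than the tachogram span")
        mask = times <= times[0] + window
        rr, times = rr[mask], times[mask]
    hr = 60000.0 / rr
    if hr.size >= 3:
        smoothed = hr.copy()
        smoothed[1:-1] = np.median(
            np.lib.stride_tricks.sliding_window_view(hr, 3), axis=1
        )
    else:
        smoothed = hr
    return float(np.max(smoothed) - np.min(smoothed))


def classify_active_sleep(obs: ObservationRecord, hrv_bpm: float) -> SleepStateResult:
    """Apply the four-criterion active-sleep rule.

    Criteria: respirations irregular, no gross body movement, eyes closed,
    and HRV strictly below 10 bpm. A missing behavioral annotation yields an
    indeterminate result (``active_sleep is None``) rather than a guess.
    """
    criteria = {
        "respirations_irregular": (
            None if obs.pattern is None else obs.pattern == PATTERN_IRREGULAR_SHALLOW
        ),
        "no_gross_movement": (
            None if obs.gross_movement is None else not obs.gross_movement
        ),
        "eyes_closed": obs.eyes_closed,
        "hrv_below_10_bpm": bool(hrv_bpm < 10.0),
    }
    if any(v is None for v in criteria.values()):
        active = None
    else:
        active = all(criteria.values())
    return SleepStateResult(
        active_sleep=active, hrv_bpm_range=float(hrv_bpm), criteria=criteria
    )
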