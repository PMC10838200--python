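"""Core in-memory containers shared by all pipeline stages.

Conventions used throughout the package:

* heart periods (R-R intervals) are in milliseconds,
* beat and sample times are in seconds from the start of the record,
* ECG voltage is in millivolts,
* power spectral densities of heart period are in ms^2/Hz.

A ``Tachogram`` anchors each R-R interval at the time of the *later* of the
two beats that delimit it, so ``beat_times`` and ``rr_ms`` always have equal
length (one fewer entry than the R-peak series they came from).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

PATTERN_REGULAR_DEEP = "regular_deep"
PATTERN_IRREGULAR_SHALLOW = "irregular_shallow"
PATTERNS = (PATTERN_REGULAR_DEEP, PATTERN_IRREGULAR_SHALLOW)

EPOCH_LABELS = ("playback_45s", "silent_300s", "other")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class ECGRecord:
    """Single-lead ECG voltage series with its sampling rate."""

    fs: float
    samples: np.ndarray
    t0: float = 0.0
    subject_id: str = ""
    epoch_label: str = "other"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = _as_float_array(self.samples, "samples")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class RPeakSeries:
    """Detected R-peak times plus per-beat detector diagnostics."""

    r_times: np.ndarray
    detection_threshold_trace: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )
    refractory_ms: float = 180.0

    def __post_init__(self) -> None:
        self.r_times = _as_float_array(self.r_times, "r_times")
        self.detection_threshold_trace = _as_float_array(
            self.detection_threshold_trace, "detection_threshold_trace"
        )
        if self.r_times.size > 1:
            gaps = np.diff(self.r_times)
            if np.any(gaps <= 0):
                raise ValueError("r_times must be strictly increasing")
            # allow a one-sample slop on the refractory floor
            if np.any(gaps < self.refractory_ms / 1000.0 - 1e-9):
                raise ValueError("successive R peaks violate the refractory period")

    def __len__(self) -> int:
        return self.r_times.size


@dataclass
class ResampledSeries:
    """Evenly resampled heart-period signal (uniform grid, step 1/rate)."""

    rate: float
    values: np.ndarray
    start: float
    end: float

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.values.size) / self.rate


@dataclass
class Tachogram:
    """R-R interval series anchored at each interval's ending beat."""

    beat_times: np.ndarray
    rr_ms: np.ndarray
    artifact_flags: Optional[np.ndarray] = None
    resampled: Optional[ResampledSeries] = None
    subject_id: str = ""
    epoch_label: str = "other"

    def __post_init__(self) -> None:
        self.beat_times = _as_float_array(self.beat_times, "beat_times")
        self.rr_ms = _as_float_array(self.rr_ms, "rr_ms")
        if self.beat_times.size != self.rr_ms.size:
            raise ValueError("beat_times and rr_ms must have equal length")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.artifact_flags is not None:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if self.artifact_flags.size != self.rr_ms.size:
                raise ValueError("artifact_flags length mismatch")

    def __len__(self) -> int:
        return self.rr_ms.size

    @property
    def span(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class SpectralEstimate:
    """One-sided PSD of the resampled heart-period signal."""

    freqs: np.ndarray
    psd: np.ndarray
    method_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = _as_float_array(self.freqs, "freqs")
        self.psd = _as_float_array(self.psd, "psd")
        if self.freqs.size != self.psd.size:
            raise ValueError("freqs and psd must have equal length")
        if np.any(self.psd < -1e-12):
            raise ValueError("psd must be non-negative")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be ascending")


@dataclass
class RSASummary:
    """Band metrics of respiratory sinus arrhythmia over [band_low, band_high].

    ``rsa_mean`` is the mean PSD ordinate in the band (ms^2/Hz), ``auc`` the
    trapezoidal band power (ms^2) and ``peak_freq`` the in-band frequency of
    maximum power (Hz, ties broken toward the lower frequency).
    """

    band: tuple = (0.30, 1.00)
    rsa_mean: float = 0.0
    auc: float = 0.0
    peak_freq: float = 0.0
    subject_id: str = ""
    epoch_label: str = "other"
    stage_parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "epoch_label": self.epoch_label,
            "band": list(self.band),
            "rsa_mean": float(self.rsa_mean),
            "auc": float(self.auc),
            "peak_freq": float(self.peak_freq),
            "stage_parameters": self.stage_parameters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSASummary":
        return cls(
            band=tuple(d.get("band", (0.30, 1.00))),
            rsa_mean=float(d["rsa_mean"]),
            auc=float(d["auc"]),
            peak_freq=float(d["peak_freq"]),
            subject_id=d.get("subject_id", ""),
            epoch_label=d.get("epoch_label", "other"),
            stage_parameters=d.get("stage_parameters", {}),
        )


@dataclass
class ObservationRecord:
    """One rater's direct observation of an infant's respiratory pattern."""

    subject_id: str
    rater_id: str
    pattern: str
    eyes_closed: Optional[bool] = None
    gross_movement: Optional[bool] = None
    epoch_label: str = "playback_45s"

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(
                f"pattern must be one of {PATTERNS}, got {self.pattern!r}"
            )


@dataclass
class SleepStateResult:
    """Outcome of the four-criterion active-sleep rule.

    ``active_sleep`` is None (indeterminate) when any behavioral annotation
    is missing; otherwise it is the conjunction of the four criteria.
    """

    active_sleep: Optional[bool]
    hrv_bpm_range: float
    criteria: dict
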