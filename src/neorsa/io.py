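"""Readers/writers for the package's CSV/JSON/YAML artifacts and run config.

CSV dialect: comma-separated, ``.`` decimal, mandatory header row. Schemas:

* ECG: ``time_s,voltage_mv``
* beat/R-R series: ``beat_time_s,rr_ms``
* observations: ``subject_id,rater_id,pattern,eyes_closed,gross_movement``

All stage parameters live in a validated :class:`RunConfig` (unknown keys
rejected, validation errors name the offending key); the config is emitted
verbatim into every results document for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .records import ECGRecord, ObservationRecord, RSASummary, SpectralEstimate, Tachogram


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterParams(_Strict):
    passband_low_hz: float = 0.5
    passband_high_hz: float = 40.0


class DetectParams(_Strict):
    refractory_ms: float = 180.0
    band_low_hz: float = 5.0
    band_high_hz: float = 20.0


class CleanParams(_Strict):
    rr_min_ms: float = 200.0
    rr_max_ms: float = 750.0
    dev_frac: float = 0.20
    max_flag_frac: float = 0.05


class SpectralParams(_Strict):
    resample_rate_hz: float = 4.0
    segment_len: int = 64
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "linear"


class BandParams(_Strict):
    low_hz: float = 0.30
    high_hz: float = 1.00


class KappaParams(_Strict):
    scheme: str = "linear"


class RunConfig(_Strict):
    """Every tunable stage parameter plus the run seed, in one document."""

    filter: FilterParams = FilterParams()
    detect: DetectParams = DetectParams()
    clean: CleanParams = CleanParams()
    spectral: SpectralParams = SpectralParams()
    band: BandParams = BandParams()
    kappa: KappaParams = KappaParams()
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def pipeline_kwargs(self) -> dict:
        """Keyword arguments for :func:`neorsa.spectral.epoch_pipeline`."""
        return dict(
            filter_passband=(self.filter.passband_low_hz, self.filter.passband_high_hz),
            refractory_ms=self.detect.refractory_ms,
            clean_bounds=(self.clean.rr_min_ms, self.clean.rr_max_ms),
            dev_frac=self.clean.dev_frac,
            resample_rate=self.spectral.resample_rate_hz,
            segment_len=self.spectral.segment_len,
            overlap=self.spectral.overlap,
            window=self.spectral.window,
            detrend=self.spectral.detrend,
            band=(self.band.low_hz, self.band.high_hz),
        )


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML or JSON; absent keys take their defaults.

    An empty file (or ``path=None``) yields the full default configuration.
    Unknown or mistyped keys raise a validation error naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            data = yaml.safe_load(text)  # YAML is a superset of JSON
            if not isinstance(data, dict):
                raise ValueError(f"config root must be a mapping, got {type(data)}")
    data.update(overrides)
    return RunConfig(**data)


# ---------------------------------------------------------------- CSV I/O

def write_ecg_csv(record: ECGRecord, path) -> None:
    pd.DataFrame({"time_s": record.times, "voltage_mv": record.samples}).to_csv(
        path, index=False
    )


def read_ecg_csv(path, fs: Optional[float] = None, **record_kwargs) -> ECGRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "voltage_mv"):
        if col not in df.columns:
            raise ValueError(f"ECG CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise ValueError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(
        fs=fs, samples=df["voltage_mv"].to_numpy(dtype=float), t0=float(t[0]),
        **record_kwargs,
    )


def write_rr_csv(t: Tachogram, path) -> None:
    pd.DataFrame({"beat_time_s": t.beat_times, "rr_ms": t.rr_ms}).to_csv(
        path, index=False
    )


def read_rr_csv(path, **kwargs) -> Tachogram:
    df = pd.read_csv(path)
    for col in ("beat_time_s", "rr_ms"):
        if col not in df.columns:
            raise ValueError(f"R-R CSV missing column {col!r}")
    return Tachogram(
        beat_times=df["beat_time_s"].to_numpy(dtype=float),
        rr_ms=df["rr_ms"].to_numpy(dtype=float),
        **kwargs,
    )


def write_observations_csv(records: Sequence[ObservationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "rater_id": r.rater_id,
                "pattern": r.pattern,
                "eyes_closed": r.eyes_closed,
                "gross_movement": r.gross_movement,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_observations_csv(path) -> list:
    df = pd.read_csv(path)
    required = {"subject_id", "rater_id", "pattern"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observations CSV missing columns {sorted(missing)}")

    def _opt_bool(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return bool(row[col])

    return [
        ObservationRecord(
            subject_id=str(row["subject_id"]),
            rater_id=str(row["rater_id"]),
            pattern=str(row["pattern"]),
            eyes_closed=_opt_bool(row, "eyes_closed"),
            gross_movement=_opt_bool(row, "gross_movement"),
        )
        for _, row in df.iterrows()
    ]


def write_psd_csv(spec: SpectralEstimate, path) -> None:
    pd.DataFrame({"freq_hz": spec.freqs, "psd_ms2_per_hz": spec.psd}).to_csv(
        path, index=False
    )


# ------------------------------------------------------------- results JSON

def write_results(
    summaries: Sequence[RSASummary],
    path,
    comparisons: Sequence = (),
    config: Optional[RunConfig] = None,
    extra: Optional[dict] = None,
) -> dict:
    """Write the schema-stable results document; returns the dict written.

    Re-reading the file reproduces every numeric field bit-exactly (JSON
    round-trips Python floats). No timestamps are embedded, so identical
    inputs yield byte-identical documents.
    """
    doc = {
        "schema": "neorsa-results-v1",
        "subjects": [s.to_dict() for s in summaries],
        "comparisons": [
            c.to_dict() if hasattr(c, "to_dict") else c for c in comparisons
        ],
        # provenance: analysis parameters only; logging verbosity and output
        # location must never alter the artifact
        "config": (
            config.model_dump(exclude={"log_level", "out_dir"})
            if config is not None
            else None
        ),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
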