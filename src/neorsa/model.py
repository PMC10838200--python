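"""Model/results front end over the analysis pipeline.

``RSAModel`` wraps one epoch of data (an ECG record, a tachogram, or a
dataframe in either schema); ``fit()`` runs the full chain — QRS detection
where needed, artifact cleaning, even resampling, Welch PSD — and returns an
:class:`RSAResults` carrying the band metrics, the spectrum, the cleaned
tachogram and a ``summary()`` table. Plotting hangs off the results object.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import RunConfig, read_ecg_csv, read_rr_csv
from .preprocess import detect_qrs, filter_ecg, rr_from_peaks
from .records import ECGRecord, RSASummary, SpectralEstimate, Tachogram
from .spectral import estimate_psd, rsa_summary
from .tachogram import clean_rr, hrv_bpm_range, resample_tachogram


class RSAModel:
    """Respiratory-sinus-arrhythmia spectral analysis of one epoch."""

    def __init__(
        self,
        data: Union[ECGRecord, Tachogram],
        config: Optional[RunConfig] = None,
        epoch_label: Optional[str] = None,
        subject_id: Optional[str] = None,
    ):
        if not isinstance(data, (ECGRecord, Tachogram)):
            raise TypeError("data must be an ECGRecord or a Tachogram")
        self.data = data
        self.config = config or RunConfig()
        self.epoch_label = epoch_label or data.epoch_label
        self.subject_id = subject_id or data.subject_id

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fs: Optional[float] = None, **kwargs
    ) -> "RSAModel":
        """Build from a dataframe with ECG or R-R schema columns."""
        if {"time_s", "voltage_mv"} <= set(df.columns):
            t = df["time_s"].to_numpy(dtype=float)
            if fs is None:
                fs = 1.0 / float(np.median(np.diff(t)))
            data: Union[ECGRecord, Tachogram] = ECGRecord(
                fs=fs, samples=df["voltage_mv"].to_numpy(dtype=float), t0=float(t[0])
            )
        elif {"beat_time_s", "rr_ms"} <= set(df.columns):
            data = Tachogram(
                beat_times=df["beat_time_s"].to_numpy(dtype=float),
                rr_ms=df["rr_ms"].to_numpy(dtype=float),
            )
        else:
            raise ValueError(
                "dataframe needs columns (time_s, voltage_mv) or (beat_time_s, rr_ms)"
            )
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, fs: Optional[float] = None, **kwargs) -> "RSAModel":
        df = pd.read_csv(path, nrows=1)
        if "voltage_mv" in df.columns:
            return cls(read_ecg_csv(path, fs=fs), **kwargs)
        return cls(read_rr_csv(path), **kwargs)

    def fit(self) -> "RSAResults":
        cfg = self.config
        if isinstance(self.data, ECGRecord):
            filtered = filter_ecg(
                self.data,
                passband=(cfg.filter.passband_low_hz, cfg.filter.passband_high_hz),
            )
            peaks = detect_qrs(filtered, refractory_ms=cfg.detect.refractory_ms)
            tacho = rr_from_peaks(
                peaks, subject_id=self.subject_id, epoch_label=self.epoch_label
            )
        else:
            peaks = None
            tacho = self.data
        cleaned = clean_rr(
            tacho,
            bounds=(cfg.clean.rr_min_ms, cfg.clean.rr_max_ms),
            dev_frac=cfg.clean.dev_frac,
            max_flag_frac=cfg.clean.max_flag_frac,
        )
        resampled = resample_tachogram(cleaned, rate=cfg.spectral.resample_rate_hz)
        spectrum = estimate_psd(
            resampled,
            segment_len=cfg.spectral.segment_len,
            overlap=cfg.spectral.overlap,
            window=cfg.spectral.window,
            detrend=cfg.spectral.detrend,
        )
        summary = rsa_summary(
            spectrum,
            band=(cfg.band.low_hz, cfg.band.high_hz),
            subject_id=self.subject_id,
            epoch_label=self.epoch_label,
        )
        summary.stage_parameters["config"] = cfg.model_dump()
        return RSAResults(
            model=self,
            rsa=summary,
            spectrum=spectrum,
            tachogram=resampled,
            peaks=peaks,
        )


class RSAResults:
    """Fitted RSA band metrics plus the intermediate pipeline products."""

    def __init__(self, model, rsa: RSASummary, spectrum: SpectralEstimate,
                 tachogram: Tachogram, peaks=None):
        self.model = model
        self.rsa = rsa
        self.spectrum = spectrum
        self.tachogram = tachogram
        self.peaks = peaks

    @property
    def rsa_mean(self) -> float:
        return self.rsa.rsa_mean

    @property
    def auc(self) -> float:
        return self.rsa.auc

    @property
    def peak_freq(self) -> float:
        return self.rsa.peak_freq

    @property
    def hrv_bpm(self) -> float:
        return hrv_bpm_range(self.tachogram)

    @property
    def n_beats(self) -> int:
        return len(self.tachogram) + 1

    def summary(self) -> str:
        lo, hi = self.rsa.band
        meta = self.spectrum.method_meta
        lines = [
            "RSA spectral analysis results",
            "=" * 46,
            f"subject: {self.rsa.subject_id or '-'}    epoch: {self.rsa.epoch_label}",
            f"beats analyzed: {self.n_beats}   "
            f"mean RR: {float(np.mean(self.tachogram.rr_ms)):.1f} ms",
            f"HRV range: {self.hrv_bpm:.2f} bpm",
            "-" * 46,
            f"band: {lo:.2f}-{hi:.2f} Hz",
            f"RSA mean magnitude: {self.rsa_mean:.3f} ms^2/Hz",
            f"band power (AUC):   {self.auc:.3f} ms^2",
            f"peak frequency:     {self.peak_freq:.4f} Hz",
            "-" * 46,
            f"Welch: {meta.get('segment_len')}-sample {meta.get('window')} segments, "
            f"{meta.get('overlap'):.0%} overlap, {meta.get('detrend')} detrend, "
            f"{meta.get('resample_rate_hz'):g} Hz resampling",
        ]
        return "\n".join(lines)

    def plot_psd(self, ax=None, shade_band: bool = True):
        """Plot the heart-period PSD with the RSA band highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.spectrum.freqs, self.spectrum.psd, lw=1.5)
        if shade_band:
            ax.axvspan(*self.rsa.band, alpha=0.15)
        ax.axvline(self.peak_freq, ls="--", lw=1)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("heart-period PSD (ms$^2$/Hz)")
        ax.set_title(f"RSA spectrum ({self.rsa.subject_id or 'epoch'})")
        return ax
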