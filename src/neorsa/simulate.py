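"""Seeded synthetic neonatal cardiorespiratory recordings.

The generator produces, per subject: a latent instantaneous heart-period
process with respiratory sinus arrhythmia (RSA) modulation, beat times via
integral pulse frequency modulation (IPFM), a rendered single-lead ECG at a
configurable sampling rate, and paired two-rater categorical observations of
the respiratory pattern.

The heart-period model is

    rr(t) = baseline_rr + resp_amp * sin(2*pi*Phi(t)) + eps(t)   [ms]

where Phi(t) integrates an instantaneous respiratory frequency f(t) that
follows a clipped Gaussian random walk started at ``resp_freq`` (step sd
``freq_jitter_sd`` every ``jitter_step`` seconds, clipped to
``freq_bounds``) and eps is white noise with sd ``noise_sd``. Two stock
scenarios mirror the qualitative respiratory regimes of interest in preterm
infants:

* scenario A, "regular deep": steady breathing near 0.30 Hz with a modest
  heart-period modulation depth;
* scenario B, "irregular shallow": faster breathing wandering around
  0.70 Hz inside 0.40-1.00 Hz, with a deeper heart-period modulation.

IPFM turns the latent process into beat times: beat k fires when the
integral of the instantaneous heart *rate* 1/rr(t) reaches k, so the
realized R-R intervals track rr(t) at the beat times.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .records import (
    ECGRecord,
    ObservationRecord,
    PATTERN_IRREGULAR_SHALLOW,
    PATTERN_REGULAR_DEEP,
)

#: minimum physiologically admissible heart period the generator will emit
RR_FLOOR_MS = 150.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic cardiorespiratory scenario.

    Units: heart periods in ms, frequencies in Hz, duration in s. The same
    (config, seed) pair always yields bit-identical output.
    """

    scenario_id: str
    baseline_rr: float
    resp_freq: float
    resp_amp: float
    freq_jitter_sd: float
    freq_bounds: tuple
    noise_sd: float
    duration: float = 45.0
    seed: int = 0
    grid_step: float = 0.010  # s, latent-process grid
    jitter_step: float = 0.25  # s, random-walk step of f(t)

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_bounds", tuple(self.freq_bounds))
        if self.baseline_rr <= 0:
            raise ValueError("baseline_rr must be positive")
        if self.resp_amp < 0:
            raise ValueError("resp_amp must be non-negative")
        if self.resp_amp >= self.baseline_rr:
            raise ValueError("resp_amp must be smaller than baseline_rr")
        lo, hi = self.freq_bounds
        if not (0.0 < lo < hi < 2.0):
            raise ValueError("freq_bounds must satisfy 0 < lo < hi < 2 Hz")
        if not (lo <= self.resp_freq <= hi):
            raise ValueError("resp_freq must lie within freq_bounds")
        if self.freq_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise standard deviations must be >= 0")
        if self.duration <= 0 or self.grid_step <= 0 or self.grid_step > 0.010 + 1e-12:
            raise ValueError("duration must be positive and grid_step <= 10 ms")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["freq_bounds"] = list(self.freq_bounds)
        return d


def scenario_a(duration: float = 45.0, seed: int = 0, **overrides) -> ScenarioConfig:
    """Regular-deep respiration: steady 0.30 Hz breathing, 10 ms RSA depth."""
    params = dict(
        scenario_id="A",
        baseline_rr=375.0,
        resp_freq=0.30,
        resp_amp=10.0,
        freq_jitter_sd=0.0,
        freq_bounds=(0.15, 0.45),
        noise_sd=2.0,
        duration=duration,
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


def scenario_b(duration: float = 45.0, seed: int = 0, **overrides) -> ScenarioConfig:
    """Irregular-shallow respiration: breathing wanders around 0.70 Hz.

    The frequency random walk (sd 0.01 Hz per 0.25 s step, clipped to
    0.40-1.00 Hz) keeps the bulk of the modulation energy near 0.70 Hz over a
    45 s epoch while still broadening the spectral band; a larger step sd
    lets the walk fill the whole band within one epoch and destroys the
    scenario's characteristic peak. The RSA depth (20 ms) is deliberately
    twice scenario A's, so band magnitude ordering is recoverable downstream.
    """
    params = dict(
        scenario_id="B",
        baseline_rr=375.0,
        resp_freq=0.70,
        resp_amp=20.0,
        freq_jitter_sd=0.010,
        freq_bounds=(0.40, 1.00),
        noise_sd=2.0,
        duration=duration,
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


def scenario_config(scenario_id: str, **kwargs) -> ScenarioConfig:
    sid = scenario_id.upper()
    if sid == "A":
        return scenario_a(**kwargs)
    if sid == "B":
        return scenario_b(**kwargs)
    raise ValueError(f"unknown scenario {scenario_id!r} (expected 'A' or 'B')")


@dataclass
class HeartPeriodProcess:
    """Latent instantaneous heart period on a fine uniform grid."""

    grid_times: np.ndarray
    rr_values: np.ndarray

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.rr_values = np.asarray(self.rr_values, dtype=float)
        if self.grid_times.size != self.rr_values.size:
            raise ValueError("grid_times and rr_values must have equal length")
        steps = np.diff(self.grid_times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("grid must be strictly increasing and uniform")
        if np.any(self.rr_values <= 0):
            raise ValueError("rr_values must be positive")

    @property
    def step(self) -> float:
        return float(self.grid_times[1] - self.grid_times[0])


def _rng_streams(seed: int, n: int) -> list:
    """Independent child generators fanned out from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_heart_period(config: ScenarioConfig) -> HeartPeriodProcess:
    """Simulate the latent heart-period process of one scenario.

    Deterministic given (config, seed); rr values are floored at
    ``RR_FLOOR_MS`` so downstream IPFM integration is always well posed.
    """
    rng_walk, rng_noise = _rng_streams(config.seed, 2)

    t = np.arange(0.0, config.duration + config.grid_step / 2, config.grid_step)

    n_steps = int(np.ceil(config.duration / config.jitter_step)) + 1
    steps = rng_walk.normal(0.0, config.freq_jitter_sd, n_steps - 1)
    walk = config.resp_freq + np.concatenate([[0.0], np.cumsum(steps)])
    walk = np.clip(walk, *config.freq_bounds)
    f_inst = np.interp(t, np.arange(n_steps) * config.jitter_step, walk)

    phase = cumulative_trapezoid(f_inst, t, initial=0.0)
    rr = config.baseline_rr + config.resp_amp * np.sin(2.0 * np.pi * phase)
    if config.noise_sd > 0:
        rr = rr + rng_noise.normal(0.0, config.noise_sd, t.size)
    return HeartPeriodProcess(grid_times=t, rr_values=np.maximum(rr, RR_FLOOR_MS))


def beat_times_from_heart_period(process: HeartPeriodProcess) -> np.ndarray:
    """Realize beat times from a heart-period process by IPFM.

    Beat k fires at the time t_k where the cumulative instantaneous rate
    integral_0^{t_k} dt / rr(t) reaches k. The integral is accumulated by the
    trapezoid rule on the process grid and inverted by linear interpolation,
    giving sub-millisecond beat-time accuracy on a 10 ms grid.
    """
    rate = 1000.0 / process.rr_values  # beats per second
    cum = cumulative_trapezoid(rate, process.grid_times, initial=0.0)
    n_beats = int(np.floor(cum[-1] + 1e-9))
    k = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(k, cum, process.grid_times)


def synthesize_ecg(
    beat_times: np.ndarray,
    fs: float = 500.0,
    qrs_amp: float = 1.0,
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
    wander_freq: float = 0.25,
    seed: int = 0,
    duration: Optional[float] = None,
    subject_id: str = "",
    epoch_label: str = "other",
) -> ECGRecord:
    """Render beat times into a synthetic single-lead ECG.

    Each beat contributes a narrow Gaussian R wave (sd 10 ms, amplitude
    ``qrs_amp`` mV) plus smaller P and T deflections; sinusoidal baseline
    wander and white noise are added on top. The clean waveform's local
    maximum stays within +/-4 ms of each beat time.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if fs < 100.0:
        raise ValueError("fs must be at least 100 Hz")
    if beat_times.size and np.any(np.diff(beat_times) < 0.120):
        raise ValueError("inter-beat gap below 120 ms: R waves would overlap")

    if duration is None:
        duration = float(beat_times[-1] + 0.3) if beat_times.size else 1.0
    if beat_times.size and beat_times[-1] > duration:
        raise ValueError("beat times extend past the record duration")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    clean = np.zeros(n)

    # (amplitude rel. qrs_amp, offset s, width sd s) for P, R, T deflections
    waves = ((0.15, -0.100, 0.020), (1.00, 0.000, 0.010), (0.25, 0.140, 0.035))
    half = 0.30  # s, support of one beat's template
    for bt in beat_times:
        i0 = max(int((bt - half) * fs), 0)
        i1 = min(int((bt + half) * fs) + 1, n)
        seg = t[i0:i1]
        for amp, off, sd in waves:
            clean[i0:i1] += qrs_amp * amp * np.exp(-0.5 * ((seg - bt - off) / sd) ** 2)

    rng = np.random.default_rng(seed)
    samples = clean
    if wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        samples = samples + wander_amp * np.sin(2 * np.pi * wander_freq * t + phase)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n)
    return ECGRecord(
        fs=fs, samples=samples, subject_id=subject_id, epoch_label=epoch_label
    )


#: ECG rendering defaults for a realistically noisy synthetic recording
DEFAULT_ECG_PARAMS = dict(
    fs=500.0, qrs_amp=1.0, noise_sd=0.05, wander_amp=0.20, wander_freq=0.25
)


def simulate_recording(
    config: ScenarioConfig,
    ecg_params: Optional[dict] = None,
    subject_id: str = "",
    epoch_label: str = "playback_45s",
):
    """Full per-subject simulation: latent process, beat times, rendered ECG.

    Returns ``(process, beat_times, ecg)``. ECG rendering noise is seeded
    from the scenario seed so the whole recording is reproducible from the
    config alone.
    """
    params = dict(DEFAULT_ECG_PARAMS)
    if ecg_params:
        params.update(ecg_params)
    process = simulate_heart_period(config)
    beats = beat_times_from_heart_period(process)
    ecg = synthesize_ecg(
        beats,
        duration=config.duration,
        seed=config.seed + 1_000_003,
        subject_id=subject_id,
        epoch_label=epoch_label,
        **params,
    )
    return process, beats, ecg


def make_observation_records(
    cohort: Sequence,
    agreement_prob: float = 0.95,
    seed: int = 0,
    eyes_closed: bool = True,
    gross_movement: bool = False,
) -> list:
    """Paired two-rater respiratory-pattern observations for a cohort.

    ``cohort`` is a sequence of ``(subject_id, scenario_id)`` pairs or
    ``ScenarioConfig`` objects (subject ids are then auto-assigned). Rater 1
    records the true scenario pattern; rater 2 agrees with probability
    ``agreement_prob`` and otherwise flips the category. Behavioral
    sleep-criteria annotations are attached to both records.
    """
    if not 0.5 <= agreement_prob <= 1.0:
        raise ValueError("agreement_prob must lie in [0.5, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for idx, item in enumerate(cohort):
        if isinstance(item, ScenarioConfig):
            subject_id, scenario_id = f"S{idx + 1:03d}", item.scenario_id
        else:
            subject_id, scenario_id = item
        true_pattern = (
            PATTERN_REGULAR_DEEP
            if scenario_id.upper() == "A"
            else PATTERN_IRREGULAR_SHALLOW
        )
        other = (
            PATTERN_IRREGULAR_SHALLOW
            if true_pattern == PATTERN_REGULAR_DEEP
            else PATTERN_REGULAR_DEEP
        )
        rater2 = true_pattern if rng.random() < agreement_prob else other
        for rater_id, pattern in (("R1", true_pattern), ("R2", rater2)):
            records.append(
                ObservationRecord(
                    subject_id=subject_id,
                    rater_id=rater_id,
                    pattern=pattern,
                    eyes_closed=eyes_closed,
                    gross_movement=gross_movement,
                )
            )
    return records


def default_cohort(
    n: int = 18, duration: float = 45.0, seed: int = 0
) -> list:
    """A balanced study cohort: n subjects alternating scenarios A and B.

    Each subject gets an independent seed derived from the cohort seed, so
    recordings are mutually independent but reproducible as a set.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    configs = []
    for i in range(n):
        maker = scenario_a if i % 2 == 0 else scenario_b
        configs.append(maker(duration=duration, seed=int(seeds[i])))
    return configs
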