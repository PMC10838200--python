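# Methods

This note documents the models, estimators and numerical choices behind
`neorsa`, in the package's own terms: what is computed, under which
assumptions, and what the synthetic test bed does and does not establish
about real neonatal recordings.

## 1. The measurement chain

The quantity of interest is respiratory sinus arrhythmia (RSA): the
modulation of heart period at the breathing frequency. The pipeline
estimates its spectral signature from a single-lead ECG in six stages, each
with an isolated, swappable implementation:

ECG → zero-phase band-pass → QRS detection → R-R tachogram → artifact
cleaning → uniform resampling → Welch PSD → band metrics over 0.30–1.00 Hz.

All heart periods are in ms, times in s, PSD in ms²/Hz.

### ECG filtering

A 4th-order Butterworth band-pass applied forward–backward
(`scipy.signal.sosfiltfilt`), default passband 0.5–40 Hz. Zero-phase
filtering preserves R-wave timing; the 0.5 Hz high-pass removes DC and
baseline wander, the 40 Hz low-pass removes high-frequency noise. Filtering
is linear and length-preserving.

### QRS detection

A Pan–Tompkins-style energy detector: band-pass 5–20 Hz (concentrates QRS
energy, rejects wander and T waves), five-point derivative, squaring, and a
centered 120 ms moving-window integral. Candidate peaks (local maxima of the
integrated energy at least one refractory period apart) are classified by an
adaptive dual threshold with the classic running updates
(`SPKI ← 0.125·v + 0.875·SPKI` on acceptance, similarly for the noise level,
threshold `NPKI + 0.25·(SPKI − NPKI)`), warm-started at 0.4 × the maximum of
the first 2 s of integrated energy. A search-back pass re-examines
sub-threshold candidates at half threshold when the gap since the last beat
exceeds 1.66 × the running mean R-R. Each accepted detection is refined to
the local maximum of the band-passed ECG within ±40 ms.

The refractory period is **180 ms**, deliberately shorter than the 200 ms
adult convention: neonatal heart rates of 160–200 bpm imply R-R intervals of
300–375 ms, and a 200 ms refractory leaves too little margin. Because the
moving-window integral is centered, its peak is aligned with the R wave and
the ±40 ms refinement window suffices.

### Tachogram construction and cleaning

R-R intervals are anchored at the time of the **later** beat of each pair
(a fixed convention required for unambiguous resampling). Cleaning flags an
interval if it is outside 200–750 ms (80–300 bpm, a generous neonatal
envelope) or if it deviates from the centered 11-interval running median by
more than 20 % of that median. Flagged intervals are repaired by linear
interpolation over beat time; if more than 5 % of intervals are flagged the
whole epoch is rejected (`EpochRejectionError`) rather than repaired, since
heavier corruption biases spectral estimates unpredictably. The rule is
idempotent.

### Resampling

The irregularly sampled tachogram is interpolated with a cubic spline onto a
uniform grid with step exactly 1/rate, restricted to the interior of the
beat-time span; the default rate of **4 Hz** puts the Nyquist frequency at
2 Hz, comfortably above the 1.0 Hz band ceiling. Cubic rather than linear
interpolation avoids the spurious high-frequency power that piecewise-linear
kinks inject inside the analysis band. End-of-interval anchoring lags the
latent modulations by about half a heart period (~190 ms); this is a pure
phase shift and does not move spectral power across frequencies.

### Spectral estimation

Welch's method: 64-sample Hann segments, 50 % overlap, per-segment linear
detrending, one-sided density scaling, PSD floored at zero. At 4 Hz this
gives a frequency resolution of 4/64 = **0.0625 Hz** — fine enough to
separate peaks at 0.30 and 0.70 Hz — while a 45 s epoch (~179 samples)
still averages four half-overlapping segments for variance reduction.
Density scaling makes the integral of the PSD match the variance of the
detrended signal (Parseval), verified in tests to 10–15 % on white noise and
to 20 % for the band power of a pure sinusoid (A²/2, window-leakage
tolerance).

### RSA band metrics

Over the band `[0.30, 1.00]` Hz, endpoints inclusive:

* `rsa_mean` — mean of the PSD ordinates at the native in-band frequency
  bins (ms²/Hz);
* `auc` — trapezoidal integral of the PSD over exactly `[0.30, 1.00]`,
  with ordinates interpolated onto the band endpoints, so a flat spectrum of
  height c integrates to exactly 0.70·c (ms²);
* `peak_freq` — the native in-band bin of maximum power, ties broken toward
  the lower frequency (Hz).

Both a mean-magnitude and a band-power reading of "RSA magnitude" are
reported because the two differ only by a near-constant factor on these
spectra and either may be the quantity a downstream consumer expects. A
natural-log option for `rsa_mean` exists but is off by default; no log
transform can be calibrated without reference units.

## 2. The synthetic cardiorespiratory generator

The generator is first-class, tested code. It emulates the latent
physiology at the level that matters for this pipeline — heart-period
modulation by respiration — and nothing more.

**Heart-period process.** On a 10 ms grid,
`rr(t) = baseline_rr + resp_amp · sin(2π Φ(t)) + ε(t)`, with
`Φ(t) = ∫ f(τ) dτ` and `f(t)` a Gaussian random walk started at
`resp_freq`, stepped every 0.25 s with sd `freq_jitter_sd` and clipped to
`freq_bounds`; ε is white with sd `noise_sd`. Values are floored at 150 ms.
Respiratory irregularity is modeled as frequency wander (not amplitude
modulation): it is the simplest mechanism that broadens the high-frequency
band the way irregular breathing does.

**Beat generation (IPFM).** Beat k fires when `∫₀^t dτ / rr(τ)` reaches k;
the integral is accumulated by the trapezoid rule and inverted by linear
interpolation, giving sub-millisecond beat-time accuracy on the 10 ms grid.
For constant rr the beats fall at exact multiples of rr, and jitter-free
configurations reproduce `baseline_rr` in the mean realized R-R to < 1 ms.

**ECG rendering.** Each beat contributes a Gaussian R wave (sd 10 ms,
default 1 mV) plus smaller P (−100 ms, 0.15 mV) and T (+140 ms, 0.25 mV)
deflections; sinusoidal baseline wander (default 0.2 mV at 0.25 Hz, random
phase) and white noise (default 0.05 mV, i.e. 5 % of the R amplitude) are
added. Sampling is 500 Hz. Beats closer than 120 ms are rejected as
physically overlapping.

**Scenarios.** Two stock configurations encode the respiratory regimes the
pipeline must distinguish, at a plausible preterm baseline of 375 ms
(~160 bpm):

| parameter | A: regular deep | B: irregular shallow |
|---|---|---|
| resp_freq | 0.30 Hz | 0.70 Hz |
| resp_amp | 10 ms | 20 ms |
| freq_jitter_sd | 0 | 0.01 Hz / 0.25 s step |
| freq_bounds | 0.15–0.45 Hz | 0.40–1.00 Hz |
| noise_sd | 2 ms | 2 ms |

No published parameter values exist for these quantities; the defaults are
chosen so that the two scenarios carry the qualitative signatures the
pipeline is meant to recover — a spectral peak at 0.30 vs. 0.70 Hz and a
strictly larger band magnitude for irregular-shallow breathing — while
remaining physiologically plausible. The scenario-B jitter was calibrated at
design time by simulation: the 50-epoch median recovered peak must sit
within one 0.0625 Hz bin of 0.70 Hz across arbitrary seed blocks. At
0.015–0.02 Hz per step the clipped walk diffuses across the whole
0.40–1.00 Hz band within a 45 s epoch and the median peak drifts low;
at 0.01 Hz per step the epoch-level wander is still substantial (~0.13 Hz
rms) but the median is stable. Scenario A's modulation depth keeps its
smoothed heart-rate range below the 10 bpm active-sleep criterion
(≈ 8.5 bpm peak-to-trough before noise); scenario B's exceeds it at times,
matching the expectation that irregular breathers show larger HRV.

**Observations.** For each subject, rater 1 records the true scenario
pattern and rater 2 agrees with probability `agreement_prob` (default 0.95),
else flips the binary category; behavioral annotations (eyes closed, no
gross movement) are attached. All randomness — walk, noise, ECG noise,
rater flips — fans out from a single seed through `numpy.random.SeedSequence`
spawning, so cohorts are reproducible while subjects stay independent.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: realistic multi-lead ECG morphology and
electrode artifacts, apneas and periodic breathing, amplitude modulation of
RSA, movement artifacts, ectopy, non-stationary baseline heart rate, and
any coupling between behavioral state and cardiac dynamics. Passing tests
show the *pipeline* is correct and self-consistent under controlled
conditions, not that the clinical discrimination would hold at a cot side.

## 3. Statistics

**HRV-in-bpm criterion.** "Heart-rate variability < 10 bpm" is read as the
range (max − min) of the 3-beat-median-smoothed instantaneous heart rate
(60000/rr) over the epoch — the natural bedside-monitor interpretation. The
first and last beats are left unsmoothed, so the definition is exactly
hand-computable. A range is only one possible reading (an SD or a monitor
trend readout are others); the definition is therefore isolated in a single
function, `hrv_bpm_range`, and consumed only through the active-sleep rule,
where the `< 10` comparison is strict.

**Active sleep** is the conjunction of four criteria — irregular
respirations, no gross movement, eyes closed, HRV < 10 bpm. A missing
behavioral annotation makes the result explicitly indeterminate rather than
defaulting either way.

**Group comparison.** Subjects are assigned to groups by rater consensus
(two-rater ties excluded, with a logged reason). RSA metrics are compared
with a two-sided Wilcoxon rank-sum (Mann–Whitney) test rather than a
t-test: groups of ~9 are small and PSD-derived metrics are right-skewed.
With fully tied samples the p-value is reported as 1. Null calibration is
verified by simulation: with both groups drawn from the same scenario, the
test rejects at the nominal 5 % level within Monte-Carlo tolerance.

**Interrater reliability.** Percent agreement plus Cohen's kappa with
disagreement weights `w_ij ∈ {0/1, |i−j|/(k−1), ((i−j)/(k−1))²}`;
linear is the default scheme (with two categories it coincides exactly with
unweighted kappa, so the choice is immaterial for the binary pattern and
becomes meaningful only for the 4-level regular/irregular × shallow/deep
extension). When both raters use one identical category, chance-corrected
agreement is undefined and reported as NaN, never as 1. The implementation
is a direct evaluation of the weighted-kappa formula; tests cross-check it
against `sklearn.metrics.cohen_kappa_score` and a hand-computed 2×2 table.

## 4. Numerical and interface choices

* Epoch lengths follow the study design the pipeline targets: 45 s
  observation epochs and 300 s silent baselines. 45 s at 4 Hz yields ~179
  resampled points — above the 64-sample Welch segment minimum with margin.
* Degenerate inputs fail loudly and specifically: short records, empty or
  constant signals, bands outside spectral support, too-few beats, windows
  longer than the record. Quality-gate failures raise `EpochRejectionError`
  carrying the failing stage's name; the CLI maps validation errors to exit
  code 2 and epoch rejections to exit code 3.
* Determinism: identical (config, seed) pairs produce bit-identical
  processes, beat times, ECGs, observations and result documents; results
  JSON contains no timestamps, and logging verbosity and output location are
  excluded from the provenance block so they can never alter an artifact.
* Test and verification problem sizes: 50 epochs per scenario for the
  peak-recovery and magnitude-ordering checks, 50 seeded recordings for QRS
  recall/precision, 200 replicates (10 + 10 subjects each) for the null
  calibration of the group test — sizes at which the Monte-Carlo error of
  each checked quantity is comfortably below its acceptance margin.

## 5. Known limitations

* The QRS detector is tuned to the synthetic morphology; on real neonatal
  ECG with ectopy or electrode artifacts its adaptive thresholds would need
  re-validation against annotated recordings.
* Equivalence with any particular legacy MATLAB implementation of the
  filtering/QRS stages cannot be claimed — only functional adequacy against
  the generator's ground truth.
* The spectral band is fixed at 0.30–1.00 Hz by design; no low-frequency
  band, LF/HF ratio or time-domain indices (SDNN, RMSSD) are computed.
* `rsa_mean` and `auc` are reported without transformation; comparisons
  across studies with unknown units require an explicit calibration the
  package does not attempt.
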