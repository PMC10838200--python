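# neorsa

Heart-rate-variability quantification of respiratory patterns in preterm
infants.

Directly observing whether a preterm infant breathes regularly and deeply or
irregularly and shallowly is subjective and labor-intensive. Because
breathing rhythmically modulates the heart period — respiratory sinus
arrhythmia (RSA), a vagally mediated high-frequency component of heart-rate
variability — the breathing pattern leaves a quantitative fingerprint in the
ECG. `neorsa` implements the full measurement chain that turns a single-lead
neonatal ECG into RSA band metrics, and the statistics used to relate those
metrics to bedside observation:

1. **ECG conditioning** — zero-phase band-pass filtering that removes
   baseline wander and out-of-band noise;
2. **QRS detection** — a Pan–Tompkins-style detector (band-pass 5–20 Hz,
   derivative, squaring, 120 ms moving-window integration, adaptive dual
   thresholds, 180 ms refractory period) producing R-peak times;
3. **Tachogram processing** — R-R intervals anchored at each interval's
   ending beat, artifact flagging/repair, cubic resampling onto a uniform
   4 Hz grid;
4. **Spectral analysis** — Welch periodogram (64-sample Hann segments, 50 %
   overlap, linear detrend; 0.0625 Hz resolution) of the heart-period
   signal, `S(f)` in ms²/Hz;
5. **RSA band metrics** over the high-frequency band `f ∈ [0.30, 1.00]` Hz:
   the mean PSD ordinate `mean S(f)`, the band power
   `AUC = ∫ S(f) df`, and the in-band peak frequency `argmax S(f)`;
6. **Group statistics** — post-hoc assignment of subjects to respiratory
   groups from two-rater observations, Wilcoxon rank-sum comparison of the
   RSA metrics, percent agreement and Cohen's weighted kappa
   `κ_w = 1 − Σ w_ij o_ij / Σ w_ij e_ij` for interrater reliability;
7. **Active-sleep rule** — the four-criterion neonatal behavioral-state
   check (irregular respirations, no gross movement, eyes closed,
   heart-rate variability < 10 bpm).

Because clinical neonatal recordings are not redistributable, the package
ships a seeded synthetic cardiorespiratory generator
(`neorsa.simulate`): a latent heart-period process with sinusoidal-to-
jittered respiratory modulation, beat times via integral pulse frequency
modulation (IPFM), and rendered 500 Hz ECG with noise and baseline wander.
Two stock scenarios encode the respiratory regimes of interest — regular
deep breathing near 0.30 Hz and irregular shallow breathing wandering
around 0.70 Hz — so every stage is testable end to end without any data
download.

The package is aimed at researchers in neonatal physiology and biosignal
processing who want a reproducible, scriptable RSA pipeline, or a controlled
test bed for HRV methodology.

## Worked example

```python
import neorsa as nr

# one irregular-shallow subject: latent process -> beats -> noisy 500 Hz ECG
cfg = nr.scenario_b(seed=1)                      # 45 s epoch
_, beats, ecg = nr.simulate_recording(cfg, subject_id="S001")

res = nr.RSAModel(ecg, subject_id="S001").fit()  # full pipeline
print(res.summary())
```

```
RSA spectral analysis results
==============================================
subject: S001    epoch: playback_45s
beats analyzed: 120   mean RR: 374.5 ms
HRV range: 11.11 bpm
----------------------------------------------
band: 0.30-1.00 Hz
RSA mean magnitude: 217.282 ms^2/Hz
band power (AUC):   162.911 ms^2
peak frequency:     0.6250 Hz
----------------------------------------------
Welch: 64-sample hann segments, 50% overlap, linear detrend, 4 Hz resampling
```

The detector found all 120 beats of this 45 s recording (~160 bpm baseline);
the 20 ms breathing modulation of heart period concentrates 163 ms² of
power in the 0.30–1.00 Hz band, peaking at 0.625 Hz for this particular
epoch of wandering respiration (the cohort median sits at 0.70 Hz, see
below). `res.plot_psd()` draws the spectrum with the band shaded.

A cohort-level analysis with grouping and reliability statistics:

```python
cohort = nr.default_cohort(n=18, seed=1)          # 9 regular + 9 irregular
obs = nr.make_observation_records(cohort, agreement_prob=0.97, seed=1)
groups, excluded = nr.assign_groups(obs)

summaries = []
for i, c in enumerate(cohort):
    _, _, ecg = nr.simulate_recording(c, subject_id=f"S{i+1:03d}")
    summaries.append(nr.epoch_pipeline(ecg, subject_id=f"S{i+1:03d}"))

print(nr.compare_rsa(summaries, groups).summary())
```

```
Two-group RSA comparison (Wilcoxon rank-sum, two-sided)
  metric tested: rsa_mean
  group 1 (regular deep): n=9, rsa_mean=46.57 (SE 0.327), auc=25.43 (SE 0.182)
  group 2 (irregular shallow): n=9, rsa_mean=205.4 (SE 4.67), auc=154 (SE 3.51)
  ratio of means (g2/g1, rsa_mean): 4.41
  U=81, p=0.0004123
```

Infants observed breathing irregularly and shallowly show a ~4.4× larger
mean RSA magnitude than the regular-deep group, and the rank-sum test
resolves the difference decisively at n = 9 + 9.

The same steps are available from a shell via the `neorsa` CLI
(`simulate`, `detect`, `analyze`, `compare`, `kappa`), e.g.

```bash
neorsa simulate --scenario B --n 9 --duration 45 --seed 1 --out cohort_b/
neorsa analyze cohort_b/ecg_S001.csv --epoch playback_45s --out s1.json
neorsa kappa --obs cohort_b/observations.csv --scheme linear
```

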