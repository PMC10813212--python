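# sleepssm

Sleep-state misperception (SSM) — reporting that you slept far less, or took
far longer to fall asleep, than the polysomnogram (PSG) shows — is a core
phenomenon of insomnia disorder. `sleepssm` is a Python package for sleep
researchers who want a reproducible, fully automated version of the analyses
typically run by hand on such datasets: misperception indices from paired
PSG/diary nights, micro-epoch alpha-density scoring, K-complex and REM-arousal
detection from raw EEG/EMG, Markov-chain analysis of stage transitions inside
the subjective sleep-onset window, and a small-sample rank-based statistics
layer — plus a deterministic synthetic-cohort generator, because clinical PSG
data of this kind usually cannot be archived publicly.

## The quantities it computes

For each subject-night with a 30-s epoch hypnogram (stages W, N1, N2, N3,
REM anchored at bedtime BT), a sleep diary, and PSG signals:

- **Misperception indices**: SLm = (SL_subj / SL_obj) × 100 (values > 100%
  mean sleep-latency overestimation) and TSTm = (TST_subj / TST_obj) × 100
  (values < 100% mean total-sleep-time underestimation), plus the raw
  discrepancy SL_subj − SL_obj used to split a cohort into lower/higher
  discrepancy groups at a 10-min cutoff.
- **Alpha density (%α)**: the fraction of 3-s micro-epochs during objective
  sleep latency containing stereotyped 8–13 Hz rhythm on an occipital lead
  for ≥ 50% of the micro-epoch, scored by a band-limited analytic envelope
  against a robust noise-floor threshold.
- **Event latencies**: latency to N1, to N3, and to the first K-complex
  (biphasic frontal waveform, 0.5–3 s, peak-to-peak amplitude gate).
- **REM arousal density (A-REMd)**: the proportion of REM epochs containing
  an arousal — a ≥ 3-s EEG frequency shift (alpha/theta or > 16 Hz, sigma
  excluded) with ≥ 1-s chin-EMG confirmation after ≥ 10 s of stable sleep.
- **Sleep-onset transition matrices**: per-subject first-order Markov
  maximum-likelihood estimates P(stage_t+1 | stage_t) within [BT, SO_subj),
  with unvisited stages kept as missing rows rather than zeros; specific
  transitions (canonically N1→W) are compared between discrepancy groups.
- **Statistics**: Mann–Whitney U (exact null for small tie-free samples)
  with rank-biserial effect size r = 2U₁/(n₁n₂) − 1, Spearman's rho with an
  exact permutation p for n ≤ 8, a Shapiro–Wilk normality gate, and OLS with
  backward elimination for the TSTm ~ A-REMd + %α + %N3 model.

## Worked example

Generate the packaged 16-subject demo cohort (8 low-discrepancy and 8
high-discrepancy subjects by construction) and analyze it:

```bash
sleepssm simulate --out demo/cohort --seed 42
sleepssm analyze --cohort demo/cohort --out demo/report
sleepssm report --run demo/report
```

which prints (abridged):

```
subjects: 16 (0 failed)
normality gate: alpha_prop=non-normal, aremd=non-normal, slm_pct=non-normal, tstm_pct=normal
spearman alpha_prop ~ slm_pct: rho=0.83 p=0.0001 (n=16)
spearman aremd ~ tstm_pct: rho=-0.67 p=0.0047 (n=16)
group comparison alpha_prop (LOW/HIGH): U=0.0 p=0.0009 r=-1.00 means=0.04/0.20
group comparison p_n1_to_w (LOW/HIGH): U=6.0 p=0.0448 r=-0.70 means=0.10/0.42
regression tstm_pct = 131.00 - 70.87*alpha_prop - 82.08*aremd (adj R2=0.59, F=11.6, dropped=['pct_n3'])
```

Reading this: subjects who overestimate their sleep latency (high SLm) show a
higher alpha density during objective sleep latency (rho = 0.83); the
higher-discrepancy group transitions from N1 back to wake far more often
during the subjective sleep-onset window (0.42 vs 0.10); and TSTm is
predicted by REM arousal density and alpha density, with the %N3 candidate
predictor eliminated. The machine-readable outputs (`subjects.csv`,
`stats.json`, `transitions.csv`, `manifest.json`) carry full precision, and
a rerun with the same seed is byte-identical.

The same `analyze` command works on real data laid out the same way: one
directory per subject with `hypnogram.csv` and signal CSVs (or EDF via
`sleepssm.events.read_signal_edf`), plus a top-level `diaries.json`.

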