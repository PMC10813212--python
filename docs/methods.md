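# Methods

This note documents the models, operational definitions, numerical choices
and limitations behind `sleepssm`. It is written for users who need to know
exactly what the package computes before trusting it on clinical data.

## Time base and hypnogram conventions

All analyses run on 30-s epoch hypnograms over the closed stage set
{W, N1, N2, N3, REM}. Epoch *i* covers the half-open interval
[30·i, 30·(i+1)) seconds from a single time origin — bedtime (BT) — shared by
the hypnogram, the diary, and every signal record. Latencies are therefore
reported at epoch-start resolution (0.5 min granularity), and objective sleep
latency SL_obj is *identically* the latency to the first non-wake epoch.
Published tables sometimes show SL shorter than latency-to-N1, which is
impossible under a single shared origin; this package deliberately adopts one
origin and exposes both quantities so the discrepancy is visible rather than
hidden in an undocumented second anchor.

WASO counts wake epochs strictly between the first and last sleep epoch (the
common convention; configurable to extend to the end of the recording), and
the awakening count is the number of maximal wake runs in that span. Stage
percentages are fractions of total sleep time, so they sum to 1 whenever any
sleep occurred. Missing values (no sleep onset, stage never reached, SLm
undefined) propagate as explicit missings, never as sentinel numbers.

## Misperception indices

SLm = (SL_subj/SL_obj)·100 and TSTm = (TST_subj/TST_obj)·100 are carried at
full precision and rounded only at report time. When a subject sleeps at the
first epoch (SL_obj = 0) the SLm ratio is undefined; the subject is excluded
from SLm analyses with a logged warning rather than imputed. The raw
discrepancy SL_subj − SL_obj splits the cohort at a 10-min cutoff; equality
at the cutoff is assigned to the lower-discrepancy group by default (the
split rule in the literature leaves the tie unassigned; the package needs a
deterministic, configurable rule).

## Automated stand-ins for visual scoring

The three EEG measures are classically scored by eye. Reproducibility
requires explicit operators, so each is defined as a deterministic algorithm
with every threshold exposed in a parameter dataclass. These are stand-ins
calibrated on synthetic signals, not validated clinical scorers.

**Alpha density.** Occipital channels are band-passed to 8–13 Hz
(4th-order Butterworth, forward–backward), and the analytic (Hilbert)
envelope is compared against k× a robust noise floor (k = 2). The floor is
the 5th percentile of per-micro-epoch median envelopes: unlike a global
median, this estimator stays anchored to the noise floor even when the
majority of micro-epochs contain alpha, which keeps the detector accurate at
coverages up to at least 90%. A 3-s micro-epoch is alpha-positive on a
channel when ≥ 50% of its envelope samples exceed threshold; labels combine
across O1/O2 with OR (visual scorers call alpha seen on either lead;
configurable to AND). Because the threshold is relative, the measure is
invariant to overall amplitude scaling. The degenerate case of a recording
that is wall-to-wall alpha defeats any self-referential baseline; scoring
such data needs k < 1 or an external baseline.

**K-complexes.** Frontal channels are band-limited to 0.3–6 Hz; candidate
troughs below −40 µV are extended to the surrounding baseline crossings and
must carry an immediately following positive component. Events are kept when
the total duration is 0.5–3 s and peak-to-peak amplitude is ≥ 75 µV, then
merged across F3/F4 (earliest start wins on overlap). The scoring manual
phrasing of the amplitude rule is sometimes printed as "≤ 75 µV", which
would reject canonical K-complexes; the package implements ≥ 75 µV as the
keep-gate and leaves the direction configurable.

**REM arousals.** The shift criterion sums envelope power over 4–11 Hz and
16–30 Hz — the 11–16 Hz gap implements the sleep-spindle exclusion as a
frequency-band exclusion rather than a spindle detector, since no spindle
algorithm is part of the definition. A candidate is a run where this power
exceeds 2× its within-REM median for ≥ 3 s, starting inside a REM epoch. It
is confirmed when chin-EMG amplitude (10 Hz high-passed, rectified, 0.5-s
smoothed) exceeds 1.5× its baseline for ≥ 1 s within the run, and the
preceding 10 s are inside the record's coverage, free of wake epochs and of
previously accepted arousals. A-REMd is the fraction of REM epochs containing
at least one arousal onset, reported as a proportion in [0, 1]; published
tables sometimes label this quantity "(%)" while printing proportion-scale
values (a regression coefficient near −56 on a predictor with mean 0.38 is
only dimensionally coherent on the proportion scale), so the package is
explicit about the scale everywhere.

## Sleep-onset Markov analysis

Within [BT, SO_subj) the stage sequence is summarised by transition counts
over consecutive epoch pairs (self-transitions included) and normalised
row-wise into maximum-likelihood probabilities. A from-stage never visited in
the window yields a missing (NaN) row, never a zero row: imputing 0 would
conflate "never left N1" with "never reached N1". Group comparisons of a
specific transition probability exclude missing-row subjects and report the
exclusion counts so a zero-imputation sensitivity analysis remains possible.
Windows holding fewer than two epochs yield a missing matrix with a warning.
The first-order (memoryless) assumption is adopted only within the
sleep-onset window, where stage dynamics are dominated by short-range
instability; it is knowingly wrong for whole-night architecture, which is why
no whole-night transition analysis is offered.

## Statistics layer

Mann–Whitney U uses the exact null distribution whenever the smaller sample
has ≤ 8 observations and the pooled data are tie-free — chosen so that
8-per-group comparisons are exact — and otherwise the tie-corrected normal
approximation with continuity correction (scipy implementations in both
branches). The rank-biserial effect size is r = 2U₁/(n₁n₂) − 1 with U₁
belonging to the first sample; the sign convention therefore follows
argument order, which the pipeline fixes as (LOW, HIGH) and records in the
report. Spearman's rho is the product-moment correlation of midranks; for
n ≤ 8 the two-sided p comes from the exhaustive n! permutation null (valid
under ties because midranks are permuted), else the t approximation. The
Shapiro–Wilk gate flags each analysis variable and the pipeline reports the
flags; following small-sample practice, the group and correlation analyses
are nonparametric regardless.

**Backward elimination.** The regression TSTm ~ A-REMd + %α + %N3 is reduced
by greedy backward elimination. The default criterion is BIC: drop the
predictor whose removal most lowers BIC, stop when no removal lowers it
(approximately "retain iff t² > ln n"). The classical adjusted-R² rule
("drop while adjusted R² increases") is available by config but is not the
default because it retains any predictor with |t| > 1 — under the null a
pure-noise predictor survives roughly a third of the time, which makes the
selected model unstable at every sample size; a p-threshold rule is also
available. The eliminated terms are returned in order in the fit's drop log.

## Synthetic cohorts

The generator produces subject-nights whose ground truth is known exactly,
emulating the study design the package targets: 16 subjects, half
low-discrepancy and half high.

- **Hypnograms**: a 20-min sleep-onset segment sampled from a group-specific
  Markov chain — the high-discrepancy chain has P(N1→W) = 0.40 against 0.02
  for the low chain — followed by a maintenance chain producing N2-dominated
  architecture with N3 and REM bouts and occasional awakenings, 840 epochs
  (7 h) in total. REM is never entered directly from wake, so every REM run
  satisfies the arousal stability precondition.
- **Signals** (100 Hz): pink-noise backgrounds at 10 µV RMS with events
  injected on schedule. Alpha bursts are 10-Hz sinusoids at 4× the median
  alpha-band noise envelope, inset 0.15 s inside their 3-s micro-epoch so
  envelope bleed cannot flip neighbouring labels; K-complexes are 1-s,
  110 µV peak-to-peak biphasic templates; arousals are an EEG shift burst
  plus a chin-EMG amplitude burst. Signals are rendered only for the windows
  the pipeline scores (the sleep-onset period and REM runs with 15 s of
  pre-roll) to keep desk-scale runtimes; a 16-subject cohort generates and
  analyzes in well under two minutes on one CPU.
- **Diaries** derive from the objective parameters through the misperception
  model SL_subj = SL_obj·exp(8·%α + ε₁) (multiplicative, because the SLm
  index is a ratio with heavy right skew; ε₁ ~ N(0, 0.25) on the log scale)
  and TST_subj = TST_obj·(132.67 − 56.04·A-REMd − 178.48·%α + ε₂)/100 with
  ε₂ ~ N(0, 15) percentage points — the published regression structure as
  generator truth, with a residual SD consistent with a model explaining
  roughly 60% of TSTm variance. Group-conditional truncation of the diary
  noise (high-discrepancy subjects floored at cutoff + 2 min above SL_obj,
  low-discrepancy capped at cutoff − 2) makes the 8/8 split exact by
  construction, as in the emulated design.

Per-subject ground truth (true alpha coverage, true A-REMd, schedules,
chains) is saved as a JSON sidecar. Generation is driven by spawned
`SeedSequence` streams, so a cohort is byte-identical under a fixed seed.

What the generator does **not** emulate: real EEG nonstationarity,
artifacts (movement, sweat, electrode pops), spindles and slow-wave
microstructure, inter-scorer variability in the hypnograms, and
night-to-night variability. Passing recovery tests therefore demonstrates
the pipeline's internal correctness — detectors recover what was injected,
estimators recover generator parameters — not clinical validity of the
detectors on real recordings.

## Numerical and degenerate-input choices

- Filters: 4th-order Butterworth sections applied forward–backward
  (zero-phase); envelopes via the analytic signal.
- Row-stochasticity is asserted to 1e-12 on every non-missing matrix row.
- Exact rank tests switch to the asymptotic branch in the presence of ties;
  identical samples yield p = 1 and r = 0.
- All-wake hypnograms yield missing SL with TST = 0 and a warning; windows
  beyond the recording end are truncated with a warning; empty windows are
  errors.
- Diary clock arithmetic wraps past midnight; all derived quantities are
  durations from BT, so wall-clock ambiguity never reaches the analyses.
- Reports round to 2 decimals only in the human-readable summary; CSV/JSON
  outputs keep full precision. No timestamps enter the manifest, keeping
  reruns byte-identical.

## Known limitations

- The detectors' default thresholds are conventional, not tuned to any
  clinical gold standard; on real data they should be calibrated against a
  scorer before the indices are interpreted.
- The alpha-density baseline is estimated within the analysis window; very
  short sleep-onset windows (< ~10 micro-epochs) give noisy floors.
- The Markov comparison inherits the small-sample fragility of its inputs:
  subjects with short subjective latency windows contribute missing rows,
  and published group summaries of bounded probabilities with SDs exceeding
  the feasible maximum for the reported mean (e.g. 0.57 ± 0.7 on [0, 1])
  cannot be reproduced by any estimator operating on [0, 1].
- A single night per subject is assumed throughout; multi-night averaging is
  out of scope.
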