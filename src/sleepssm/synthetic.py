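"""Synthetic subject-nights with known ground truth.

Real polysomnographic recordings of the kind this package analyses are
sensitive clinical data and are typically not publicly archivable, so every
stage of the pipeline is exercised against synthetic subject-nights whose
ground truth is known by construction:

* **Hypnograms** are sampled from explicit first-order Markov chains — a
  sleep-onset chain (group-specific: the higher-discrepancy group's chain has
  a much larger N1→W probability) followed by a sleep-maintenance chain that
  produces N2/N3/REM architecture with occasional awakenings.
* **EEG/EMG signals** are 1/f (pink) noise backgrounds with alpha bursts,
  biphasic K-complex templates, and arousal bursts (EEG frequency shift plus
  chin-EMG burst) injected at scheduled times, so detector recovery can be
  scored against the schedule.
* **Diaries** derive from the objective parameters through an explicit
  misperception model: multiplicative on sleep latency (the latency
  misperception index is a ratio with heavy right skew), linear on the
  percentage scale for total sleep time — with the published regression
  structure as the default generator coefficients.

Everything is deterministic under a fixed seed; a cohort regenerated from the
same configuration is byte-identical on disk.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .diary import SleepDiary, add_minutes
from .errors import ValidationError
from .events import (
    CHIN_EMG,
    FRONTAL,
    OCCIPITAL,
    SignalRecord,
    write_signal_csv,
    _bandpass,
    _envelope,
)
from .hypnogram import (
    STAGE_ORDER,
    Anchor,
    Hypnogram,
    ObjectiveSleepParams,
    Stage,
    objective_sleep_params,
    write_hypnogram_csv,
)

__all__ = [
    "MisperceptionModel",
    "CohortConfig",
    "SubjectNight",
    "ONSET_CHAIN_LOW",
    "ONSET_CHAIN_HIGH",
    "MAINTENANCE_CHAIN",
    "generate_hypnogram",
    "generate_eeg",
    "generate_diary",
    "generate_cohort",
    "write_cohort",
]

_INDEX = {s: i for i, s in enumerate(STAGE_ORDER)}

# Sleep-onset chains (rows/cols W, N1, N2, N3, REM).  The low-discrepancy
# chain settles from W into consolidated N1/N2; the high-discrepancy chain
# keeps bouncing from N1 back to W, mirroring the onset instability that
# accompanies latency overestimation.
ONSET_CHAIN_LOW = np.array(
    [
        [0.90, 0.08, 0.02, 0.00, 0.00],
        [0.02, 0.78, 0.20, 0.00, 0.00],
        [0.01, 0.02, 0.95, 0.02, 0.00],
        [0.00, 0.00, 0.05, 0.95, 0.00],
        [0.00, 0.05, 0.05, 0.00, 0.90],
    ]
)

ONSET_CHAIN_HIGH = np.array(
    [
        [0.88, 0.11, 0.01, 0.00, 0.00],
        [0.40, 0.45, 0.15, 0.00, 0.00],
        [0.05, 0.10, 0.83, 0.02, 0.00],
        [0.00, 0.00, 0.05, 0.95, 0.00],
        [0.00, 0.05, 0.05, 0.00, 0.90],
    ]
)

# Whole-night maintenance chain: N2-dominated with N3 and REM bouts and
# occasional awakenings; REM is never entered directly from W so that every
# REM run is preceded by sleep (as required by the arousal stability rule).
MAINTENANCE_CHAIN = np.array(
    [
        [0.800, 0.150, 0.050, 0.000, 0.000],
        [0.050, 0.600, 0.350, 0.000, 0.000],
        [0.020, 0.030, 0.880, 0.050, 0.020],
        [0.005, 0.005, 0.070, 0.920, 0.000],
        [0.020, 0.020, 0.030, 0.000, 0.930],
    ]
)


def _check_chain(chain: np.ndarray) -> np.ndarray:
    chain = np.asarray(chain, dtype=float)
    if chain.shape != (5, 5) or (chain < 0).any():
        raise ValidationError("transition chain must be a non-negative 5x5 matrix")
    sums = chain.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValidationError(f"chain rows must sum to 1, got {sums}")
    return chain


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MisperceptionModel:
    """Maps objective sleep parameters plus EEG indices to diary values.

    ``SL_subj = SL_obj * exp(slm_slope * alpha_prop + e1)`` with
    ``e1 ~ N(0, sl_noise_sd)`` on the log scale, and
    ``TST_subj = TST_obj * (tstm_intercept + tstm_beta_aremd * aremd +
    tstm_beta_alpha * alpha_prop + e2) / 100`` with ``e2 ~ N(0,
    tst_noise_pct_sd)`` on the percentage scale, floored at zero.  The TST
    coefficients default to the published regression structure of the study
    design this generator emulates.
    """

    slm_slope: float = 8.0
    tstm_intercept: float = 132.67
    tstm_beta_aremd: float = -56.04
    tstm_beta_alpha: float = -178.48
    sl_noise_sd: float = 0.25
    tst_noise_pct_sd: float = 15.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort (defaults = study design).

    Sixteen subjects, half generated with low-discrepancy settings and half
    with high, emulating the 8/8 split of the design; alpha-density ranges
    reflect the reported subgroup values (~2.6% vs ~16.5%), the REM-arousal
    density range brackets the reported mean 0.38 ± 0.19, and the first
    K-complex latency range brackets the reported 26.7 ± 18 min.
    """

    n_subjects: int = 16
    seed: int = 0
    onset_chain_low: np.ndarray = field(default_factory=lambda: ONSET_CHAIN_LOW.copy())
    onset_chain_high: np.ndarray = field(default_factory=lambda: ONSET_CHAIN_HIGH.copy())
    alpha_prop_range_low: Tuple[float, float] = (0.0, 0.08)
    alpha_prop_range_high: Tuple[float, float] = (0.10, 0.30)
    aremd_range: Tuple[float, float] = (0.10, 0.70)
    kc_first_latency_range_min: Tuple[float, float] = (8.0, 30.0)
    misperception_model: MisperceptionModel = field(default_factory=MisperceptionModel)
    n_epochs: int = 840
    n_onset_epochs: int = 40
    epoch_len_s: float = 30.0
    fs_hz: float = 100.0
    bt_clock: str = "23:30"
    cutoff_min: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("cohort needs at least 2 subjects")
        _check_chain(self.onset_chain_low)
        _check_chain(self.onset_chain_high)
        for name in ("alpha_prop_range_low", "alpha_prop_range_high", "aremd_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"{name} must be within [0, 1], got ({lo}, {hi})")


@dataclass
class SubjectNight:
    """One generated subject-night with its ground truth."""

    subject_id: str
    hypnogram: Hypnogram
    diary: SleepDiary
    signals: Dict[str, SignalRecord]
    truth: dict


# ---------------------------------------------------------------------------
# hypnogram generation
# ---------------------------------------------------------------------------

def generate_hypnogram(
    chain: np.ndarray,
    n_epochs: int,
    start: Stage = Stage.W,
    seed: Union[int, np.random.Generator] = 0,
    epoch_len_s: float = 30.0,
    anchor: Optional[Anchor] = None,
) -> Hypnogram:
    """Sample a first-order Markov stage sequence of ``n_epochs`` epochs."""
    chain = _check_chain(chain)
    if n_epochs < 2:
        raise ValidationError(f"need n_epochs >= 2, got {n_epochs}")
    rng = _rng(seed)
    seq = _sample_chain(chain, n_epochs, start, rng)
    return Hypnogram(tuple(seq), epoch_len_s=epoch_len_s, anchor=anchor or Anchor())


def _sample_chain(
    chain: np.ndarray, n_epochs: int, start: Stage, rng: np.random.Generator
) -> List[Stage]:
    cum = np.cumsum(chain, axis=1)
    states = [start]
    i = _INDEX[start]
    draws = rng.random(n_epochs - 1)
    for u in draws:
        i = int(np.searchsorted(cum[i], u, side="right"))
        i = min(i, 4)
        states.append(STAGE_ORDER[i])
    return states


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator, rms: float) -> np.ndarray:
    """1/f-amplitude noise normalised to the requested RMS."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spectrum /= np.sqrt(freqs)
    x = np.fft.irfft(spectrum, n)
    return x * (rms / np.std(x))


def _kc_template(fs: float, dur_s: float, pp_uv: float) -> np.ndarray:
    """Biphasic K-complex: sharp negative lobe then a positive component."""
    n1 = int(round(0.45 * dur_s * fs))
    n2 = int(round(0.55 * dur_s * fs))
    a_neg, a_pos = 0.6 * pp_uv, 0.4 * pp_uv
    neg = -a_neg * np.sin(np.pi * np.arange(n1) / n1)
    pos = a_pos * np.sin(np.pi * np.arange(n2) / n2)
    return np.concatenate([neg, pos])


def generate_eeg(
    duration_s: float,
    fs_hz: float = 100.0,
    alpha_schedule: Sequence[Tuple[float, float]] = (),
    kc_times: Sequence[float] = (),
    arousal_schedule: Sequence[Tuple[Tuple[float, float], bool]] = (),
    seed: Union[int, np.random.Generator] = 0,
    t0_s: float = 0.0,
    roles: Sequence[str] = (OCCIPITAL, FRONTAL, CHIN_EMG),
    noise_rms_uv: float = 10.0,
    alpha_snr: float = 4.0,
    alpha_hz: float = 10.0,
    kc_pp_uv: float = 110.0,
    kc_dur_s: float = 1.0,
    emg_noise_rms_uv: float = 2.0,
    emg_burst_rms_uv: float = 8.0,
) -> Tuple[SignalRecord, dict]:
    """Render a signal record from event schedules over a noise background.

    Schedules are in seconds on the same time base as ``t0_s`` (i.e. from the
    hypnogram anchor).  Alpha bursts are ``alpha_hz`` sinusoids whose
    amplitude is ``alpha_snr`` times the median alpha-band noise envelope;
    arousal entries are ``((start_s, end_s), emg)`` pairs adding an EEG
    frequency shift plus (when ``emg`` is true) a chin-EMG burst.  Returns
    the record together with the ground-truth schedule.
    """
    rng = _rng(seed)
    n = int(round(duration_s * fs_hz))
    t_rel = np.arange(n) / fs_hz
    channels: Dict[str, np.ndarray] = {}
    role_map: Dict[str, List[str]] = {}

    def _sec_to_idx(s: float) -> int:
        return int(round((s - t0_s) * fs_hz))

    for s in list(kc_times):
        if not (t0_s <= s <= t0_s + duration_s):
            raise ValidationError(f"K-complex time {s} s outside the record")

    def _add_burst(x: np.ndarray, start_s: float, end_s: float, amp: float) -> None:
        a, b = max(0, _sec_to_idx(start_s)), min(n, _sec_to_idx(end_s))
        if b <= a:
            return
        seg_t = t_rel[a:b]
        win = np.hanning(max(b - a, 2)) ** 0.25  # gentle taper, near-flat top
        x[a:b] += amp * win * np.sin(2 * np.pi * alpha_hz * seg_t)

    if OCCIPITAL in roles:
        names = ["O1", "O2"]
        role_map[OCCIPITAL] = names
        for name in names:
            x = _pink_noise(n, rng, noise_rms_uv)
            env = _envelope(_bandpass(x, fs_hz, 8.0, 13.0))
            alpha_amp = alpha_snr * float(np.median(env))
            for start_s, end_s in alpha_schedule:
                _add_burst(x, start_s, end_s, alpha_amp)
            shift_amp = 6.0 * float(np.median(env))
            for (start_s, end_s), _emg in arousal_schedule:
                _add_burst(x, start_s, end_s, shift_amp)
            channels[name] = x

    if FRONTAL in roles:
        names = ["F3", "F4"]
        role_map[FRONTAL] = names
        template = _kc_template(fs_hz, kc_dur_s, kc_pp_uv)
        for name in names:
            x = _pink_noise(n, rng, noise_rms_uv)
            last_end = -np.inf
            for s in sorted(kc_times):
                a = _sec_to_idx(s)
                b = min(a + len(template), n)
                if a < last_end:
                    warnings.warn(
                        f"overlapping K-complex templates at {s} s; rendered additively",
                        stacklevel=2,
                    )
                if 0 <= a < n:
                    x[a:b] += template[: b - a]
                last_end = a + len(template)
            channels[name] = x

    if CHIN_EMG in roles:
        role_map[CHIN_EMG] = ["EMG"]
        x = rng.standard_normal(n) * emg_noise_rms_uv
        for (start_s, end_s), emg in arousal_schedule:
            if not emg:
                continue
            a, b = max(0, _sec_to_idx(start_s)), min(n, _sec_to_idx(end_s))
            if b > a:
                x[a:b] += rng.standard_normal(b - a) * emg_burst_rms_uv
        channels["EMG"] = x

    record = SignalRecord(channels=channels, fs_hz=fs_hz, roles=role_map, t0_s=t0_s)
    truth = {
        "alpha_schedule": [list(iv) for iv in alpha_schedule],
        "kc_times": sorted(float(s) for s in kc_times),
        "arousal_schedule": [[list(iv), bool(e)] for iv, e in arousal_schedule],
    }
    return record, truth


# ---------------------------------------------------------------------------
# diary generation
# ---------------------------------------------------------------------------

def generate_diary(
    obj: ObjectiveSleepParams,
    alpha_prop: float,
    aremd: float,
    model: MisperceptionModel = MisperceptionModel(),
    seed: Union[int, np.random.Generator] = 0,
    subject_id: str = "",
    bt_clock: str = "23:30",
) -> SleepDiary:
    """Draw a subjective diary from objective parameters via the misperception model."""
    if obj.sl_obj_min is None or obj.sl_obj_min <= 0:
        raise ValidationError("diary generation requires SL_obj > 0")
    if obj.tst_obj_min <= 0:
        raise ValidationError("diary generation requires TST_obj > 0")
    rng = _rng(seed)
    e1 = rng.normal(0.0, model.sl_noise_sd) if model.sl_noise_sd > 0 else 0.0
    e2 = rng.normal(0.0, model.tst_noise_pct_sd) if model.tst_noise_pct_sd > 0 else 0.0
    sl_subj = obj.sl_obj_min * np.exp(model.slm_slope * alpha_prop + e1)
    tstm_pct = (
        model.tstm_intercept
        + model.tstm_beta_aremd * aremd
        + model.tstm_beta_alpha * alpha_prop
        + e2
    )
    tst_subj = max(0.0, obj.tst_obj_min * tstm_pct / 100.0)
    waso_subj = max(0.0, obj.waso_obj_min * float(np.exp(rng.normal(-0.45, 0.3))))
    nawk_subj = max(0, int(round(obj.nawk_obj * float(rng.uniform(0.5, 1.0)))))
    final_wake = add_minutes(bt_clock, obj.sl_obj_min + obj.tst_obj_min + obj.waso_obj_min)
    return SleepDiary(
        subject_id=subject_id,
        bt_clock=bt_clock,
        sl_subj_min=float(sl_subj),
        tst_subj_min=float(tst_subj),
        waso_subj_min=float(waso_subj),
        nawk_subj=nawk_subj,
        final_wake_clock=final_wake,
        out_of_bed_clock=add_minutes(final_wake, 10),
        completed_within_min=5.0,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _rem_runs(epochs: Sequence[Stage]) -> List[Tuple[int, int]]:
    runs, start = [], None
    for i, s in enumerate(epochs):
        if s is Stage.REM and start is None:
            start = i
        elif s is not Stage.REM and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(epochs)))
    return runs


def _generate_subject(
    i: int, cfg: CohortConfig, rng: np.random.Generator
) -> SubjectNight:
    high = i >= cfg.n_subjects // 2
    group = "HIGH" if high else "LOW"
    sid = f"sub-{i + 1:02d}"
    chain = cfg.onset_chain_high if high else cfg.onset_chain_low

    # hypnogram: onset-chain segment, then maintenance architecture
    for _ in range(50):
        onset = _sample_chain(chain, cfg.n_onset_epochs, Stage.W, rng)
        if any(s is not Stage.W for s in onset):
            break
    else:  # pragma: no cover - ~0.9^40 per try
        onset[-1] = Stage.N1
    night = _sample_chain(MAINTENANCE_CHAIN, cfg.n_epochs - cfg.n_onset_epochs, Stage.N2, rng)
    anchor = Anchor("BEDTIME", cfg.bt_clock)
    hyp = Hypnogram(tuple(onset + night), epoch_len_s=cfg.epoch_len_s, anchor=anchor)
    obj = objective_sleep_params(hyp)
    sl_obj = obj.sl_obj_min
    fs = cfg.fs_hz

    # alpha schedule over the objective sleep-latency window
    lo, hi = cfg.alpha_prop_range_high if high else cfg.alpha_prop_range_low
    alpha_target = float(rng.uniform(lo, hi))
    n_micro = int(np.floor(sl_obj * 60.0 / 3.0))
    k_alpha = int(round(alpha_target * n_micro))
    chosen_micro = np.sort(rng.choice(n_micro, size=k_alpha, replace=False)) if k_alpha else np.array([], dtype=int)
    alpha_true = k_alpha / n_micro if n_micro else 0.0
    alpha_schedule = [(m * 3.0 + 0.15, (m + 1) * 3.0 - 0.15) for m in chosen_micro]

    # K-complex times (first anchors the latency measure)
    kc_first_s = float(rng.uniform(*cfg.kc_first_latency_range_min)) * 60.0
    kc_times = [kc_first_s]
    for _ in range(2):
        kc_times.append(kc_times[-1] + float(rng.uniform(40.0, 90.0)))
    onset_dur = max(sl_obj * 60.0, kc_times[-1] + 5.0) + 10.0

    onset_sig, onset_truth = generate_eeg(
        duration_s=onset_dur,
        fs_hz=fs,
        alpha_schedule=alpha_schedule,
        kc_times=kc_times,
        seed=rng,
        roles=(OCCIPITAL, FRONTAL),
    )

    # REM arousal schedule over REM epochs of the whole night
    rem_epochs = [j for j, s in enumerate(hyp.epochs) if s is Stage.REM]
    eligible = [j for j in rem_epochs if j > 0 and hyp.epochs[j - 1] is not Stage.W]
    aremd_target = float(rng.uniform(*cfg.aremd_range))
    k_ar = min(int(round(aremd_target * len(rem_epochs))), len(eligible))
    chosen_epochs = sorted(rng.choice(len(eligible), size=k_ar, replace=False).tolist()) if k_ar else []
    chosen_epochs = [eligible[j] for j in chosen_epochs]
    aremd_true = k_ar / len(rem_epochs) if rem_epochs else 0.0

    signals = {"onset": onset_sig}
    arousal_truth = []
    epl = cfg.epoch_len_s
    for r, (a, b) in enumerate(_rem_runs(hyp.epochs)):
        seg_sched = [
            ((j * epl + 12.0, j * epl + 17.0), True) for j in chosen_epochs if a <= j < b
        ]
        t0 = a * epl - 15.0
        seg, seg_truth = generate_eeg(
            duration_s=b * epl - t0,
            fs_hz=fs,
            arousal_schedule=seg_sched,
            seed=rng,
            t0_s=t0,
            roles=(OCCIPITAL, CHIN_EMG),
        )
        signals[f"rem_{r:02d}"] = seg
        arousal_truth.extend(seg_truth["arousal_schedule"])

    diary = generate_diary(
        obj,
        alpha_true,
        aremd_true,
        cfg.misperception_model,
        seed=rng,
        subject_id=sid,
        bt_clock=cfg.bt_clock,
    )
    # group-conditional truncation: the emulated design fixes the
    # discrepancy split, so the diary noise may not move a subject across
    # the cutoff
    if high:
        sl_subj = max(diary.sl_subj_min, sl_obj + cfg.cutoff_min + 2.0)
    else:
        sl_subj = min(diary.sl_subj_min, sl_obj + cfg.cutoff_min - 2.0)
    sl_subj = max(sl_subj, 1.5)
    if sl_subj != diary.sl_subj_min:
        diary = SleepDiary(
            subject_id=diary.subject_id,
            bt_clock=diary.bt_clock,
            sl_subj_min=float(sl_subj),
            tst_subj_min=diary.tst_subj_min,
            waso_subj_min=diary.waso_subj_min,
            nawk_subj=diary.nawk_subj,
            final_wake_clock=diary.final_wake_clock,
            out_of_bed_clock=diary.out_of_bed_clock,
            completed_within_min=diary.completed_within_min,
        )

    truth = {
        "group": group,
        "alpha_prop": alpha_true,
        "aremd": aremd_true,
        "sl_obj_min": sl_obj,
        "tst_obj_min": obj.tst_obj_min,
        "kc_first_latency_min": kc_first_s / 60.0,
        "n_rem_epochs": len(rem_epochs),
        "alpha_schedule": onset_truth["alpha_schedule"],
        "kc_times": onset_truth["kc_times"],
        "arousal_schedule": arousal_truth,
    }
    return SubjectNight(subject_id=sid, hypnogram=hyp, diary=diary, signals=signals, truth=truth)


def generate_cohort(cfg: CohortConfig) -> List[SubjectNight]:
    """Generate ``cfg.n_subjects`` subject-nights (first half LOW, second half HIGH)."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    return [
        _generate_subject(i, cfg, np.random.default_rng(children[i]))
        for i in range(cfg.n_subjects)
    ]


def write_cohort(subjects: Sequence[SubjectNight], outdir: Union[str, Path]) -> Path:
    """Write a cohort in the formats the ingestion modules read.

    Layout: ``diaries.json`` at the top level; per subject a directory with
    ``hypnogram.csv``, one CSV per signal record, and a ``truth.json``
    ground-truth sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diaries = []
    for s in subjects:
        d = s.diary
        diaries.append(
            {
                "subject_id": d.subject_id,
                "bt": d.bt_clock,
                "sl_subj_min": round(d.sl_subj_min, 4),
                "tst_subj_min": round(d.tst_subj_min, 4),
                "waso_subj_min": None if d.waso_subj_min is None else round(d.waso_subj_min, 4),
                "nawk_subj": d.nawk_subj,
                "final_wake": d.final_wake_clock,
                "out_of_bed": d.out_of_bed_clock,
                "completed_within_min": d.completed_within_min,
            }
        )
        subdir = outdir / s.subject_id
        subdir.mkdir(exist_ok=True)
        write_hypnogram_csv(s.hypnogram, subdir / "hypnogram.csv")
        for name, sig in sorted(s.signals.items()):
            write_signal_csv(sig, subdir / f"{name}.csv", float_format="%.2f")
        with open(subdir / "truth.json", "wt", encoding="utf-8") as fh:
            json.dump(s.truth, fh, indent=1, sort_keys=True)
    with open(outdir / "diaries.json", "wt", encoding="utf-8") as fh:
        json.dump(diaries, fh, indent=1, sort_keys=True)
    return outdir
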