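"""Automated detectors for visually scored sleep-EEG measures.

Three micro-structure measures are computed from raw signals:

* **Alpha density (%α)** — the fraction of 3-s micro-epochs inside a window
  (canonically the objective sleep-latency period) that contain stereotyped
  8–13 Hz alpha rhythm on an occipital derivation for at least half of the
  micro-epoch.  Scored here via the band-limited analytic envelope against a
  robust noise-floor threshold, so the measure is invariant to overall
  amplitude scaling.
* **K-complexes** — biphasic frontal waveforms (sharp negative deflection
  immediately followed by a positive component), 0.5–3 s long, with a
  peak-to-peak amplitude gate (default ≥ 75 µV).  The first K-complex anchors
  one of the latency-to-stage measures.
* **REM arousals** — abrupt EEG frequency shifts toward alpha/theta or
  > 16 Hz activity (the 11–16 Hz sigma/spindle band is excluded from the
  shift criterion), lasting ≥ 3 s, accompanied by a ≥ 1-s rise in chin-EMG
  amplitude, after ≥ 10 s of stable sleep.  Their density over REM epochs is
  the REM arousal density (A-REMd), reported as a proportion in [0, 1].

All thresholds live in parameter dataclasses; the defaults are conventional
automated-scoring choices, not clinical ground truth.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import RoleError, StructureError, ValidationError
from .hypnogram import Hypnogram, Stage

__all__ = [
    "SignalRecord",
    "AlphaParams",
    "KCParams",
    "ArousalParams",
    "AlphaDensityResult",
    "KComplexEvent",
    "ArousalEvent",
    "alpha_density",
    "detect_kcomplexes",
    "first_kc_latency",
    "detect_rem_arousals",
    "rem_arousal_density",
    "read_signal_csv",
    "write_signal_csv",
    "read_signal_edf",
    "events_to_frame",
]

OCCIPITAL = "occipital"
FRONTAL = "frontal"
CHIN_EMG = "chin_emg"


@dataclass
class SignalRecord:
    """Multichannel sampled physiological signals with channel roles.

    ``channels`` maps channel name to a 1-D float array in µV; all channels
    share ``fs_hz``.  ``roles`` maps a role (``occipital``, ``frontal``,
    ``chin_emg``) to the channel names serving it.  ``t0_s`` is the offset of
    sample 0 from the hypnogram anchor, so a record may cover only the
    analysed windows of the night.
    """

    channels: Dict[str, np.ndarray]
    fs_hz: float
    roles: Dict[str, List[str]]
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz < 100:
            raise ValidationError(
                f"fs_hz must be >= 100 to resolve alpha and >16 Hz activity, got {self.fs_hz}"
            )
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"channels differ in length: {lengths}")
        self.channels = {name: np.asarray(x, dtype=float) for name, x in self.channels.items()}
        for role, names in self.roles.items():
            for name in names:
                if name not in self.channels:
                    raise RoleError(f"role {role!r} references unknown channel {name!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def role_channels(self, role: str) -> List[str]:
        names = self.roles.get(role, [])
        if not names:
            raise RoleError(f"signal record has no channel with role {role!r}")
        return names


@dataclass(frozen=True)
class AlphaParams:
    """Alpha-density scoring parameters.

    The threshold is ``k`` times a robust noise-floor estimate of the
    band-limited envelope.  The default estimator takes the per-micro-epoch
    median envelope and uses a low quantile across micro-epochs, which stays
    anchored to the noise floor even when most micro-epochs contain alpha.
    """

    band_hz: Tuple[float, float] = (8.0, 13.0)
    micro_epoch_s: float = 3.0
    min_fraction: float = 0.5
    k: float = 2.0
    baseline: str = "micro_median_quantile"  # or "global_median"
    baseline_quantile: float = 0.05
    combine: str = "or"  # label = OR/AND across occipital channels


@dataclass(frozen=True)
class KCParams:
    """K-complex detection parameters (band-limited trough-and-rebound search)."""

    band_hz: Tuple[float, float] = (0.3, 6.0)
    amp_neg_uv: float = 40.0
    min_pp_uv: float = 75.0
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0


@dataclass(frozen=True)
class ArousalParams:
    """REM-arousal detection parameters.

    ``shift_bands_hz`` define the frequency content that counts toward the
    shift criterion (alpha/theta and >16 Hz); sigma/spindle frequencies
    (11–16 Hz) are deliberately between the two bands and therefore excluded.
    """

    shift_bands_hz: Tuple[Tuple[float, float], ...] = ((4.0, 11.0), (16.0, 30.0))
    power_factor: float = 2.0
    min_shift_s: float = 3.0
    emg_factor: float = 1.5
    min_emg_s: float = 1.0
    stable_s: float = 10.0
    smooth_s: float = 0.5
    emg_highpass_hz: float = 10.0


@dataclass(frozen=True)
class AlphaDensityResult:
    """Outcome of micro-epoch alpha scoring over one window."""

    alpha_prop: float
    micro_labels: np.ndarray
    n_micro: int
    window_min: Tuple[float, float]


@dataclass(frozen=True)
class KComplexEvent:
    t_start_s: float
    t_end_s: float
    peak_to_peak_uv: float
    channel: str

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass(frozen=True)
class ArousalEvent:
    t_start_s: float
    t_end_s: float
    stage_context: Stage
    emg_confirmed: bool

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(sps.hilbert(x))


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


# ---------------------------------------------------------------------------
# alpha density
# ---------------------------------------------------------------------------

def alpha_density(
    sig: SignalRecord,
    window_min: Tuple[float, float],
    params: AlphaParams = AlphaParams(),
) -> AlphaDensityResult:
    """Score 3-s micro-epochs for stereotyped alpha and return their density.

    The window is in minutes from the hypnogram anchor and must lie inside
    the record's coverage.  A micro-epoch is alpha-positive on a channel when
    at least ``min_fraction`` of its samples exceed ``k`` times the robust
    baseline envelope; labels are combined across occipital channels with
    OR (default) or AND.
    """
    names = sig.role_channels(OCCIPITAL)
    start_s, end_s = window_min[0] * 60.0, window_min[1] * 60.0
    if end_s - start_s < params.micro_epoch_s:
        raise ValidationError(
            f"window of {end_s - start_s:g} s is shorter than one "
            f"{params.micro_epoch_s:g}-s micro-epoch"
        )
    i0 = int(round((start_s - sig.t0_s) * sig.fs_hz))
    i1 = int(round((end_s - sig.t0_s) * sig.fs_hz))
    if i0 < 0 or i1 > sig.n_samples:
        raise ValidationError(
            f"window [{window_min[0]:g}, {window_min[1]:g}] min outside record coverage"
        )

    n_per = int(round(params.micro_epoch_s * sig.fs_hz))
    n_micro = (i1 - i0) // n_per

    per_channel = []
    for name in names:
        x = sig.channels[name][i0 : i0 + n_micro * n_per]
        env = _envelope(_bandpass(x, sig.fs_hz, *params.band_hz))
        env_micro = env.reshape(n_micro, n_per)
        if params.baseline == "micro_median_quantile":
            floors = np.median(env_micro, axis=1)
            baseline = float(np.quantile(floors, params.baseline_quantile))
        elif params.baseline == "global_median":
            baseline = float(np.median(env))
        else:
            raise ValidationError(f"unknown baseline estimator {params.baseline!r}")
        thresh = params.k * baseline
        frac_above = np.mean(env_micro > thresh, axis=1)
        per_channel.append(frac_above >= params.min_fraction)

    stacked = np.vstack(per_channel)
    labels = stacked.any(axis=0) if params.combine == "or" else stacked.all(axis=0)
    return AlphaDensityResult(
        alpha_prop=float(labels.mean()),
        micro_labels=labels,
        n_micro=n_micro,
        window_min=(window_min[0], window_min[1]),
    )


# ---------------------------------------------------------------------------
# K-complexes
# ---------------------------------------------------------------------------

def _detect_kc_channel(
    x: np.ndarray, fs: float, params: KCParams, name: str, t0_s: float
) -> List[KComplexEvent]:
    y = _bandpass(x, fs, *params.band_hz)
    troughs, _ = sps.find_peaks(-y, height=params.amp_neg_uv)
    events: List[KComplexEvent] = []
    last_end = -1
    neg = y < 0
    for t in troughs:
        if t <= last_end:  # trough inside an already accepted event
            continue
        # onset: last non-negative sample before the trough
        before = np.nonzero(~neg[:t])[0]
        if len(before) == 0:
            continue
        a = before[-1]
        # rebound: first zero-upcrossing after the trough
        after = np.nonzero(~neg[t:])[0]
        if len(after) == 0:
            continue
        b = t + after[0]
        # positive component: from b until the signal returns below zero
        pos_run = np.nonzero(y[b:] <= 0)[0]
        c = b + (pos_run[0] if len(pos_run) else len(y) - b)
        if c <= b:
            continue
        pos_peak = float(np.max(y[b:c]))
        if pos_peak <= 0:
            continue
        dur = (c - a) / fs
        pp = pos_peak - float(y[t])
        if params.min_dur_s <= dur <= params.max_dur_s and pp >= params.min_pp_uv:
            events.append(
                KComplexEvent(
                    t_start_s=t0_s + a / fs,
                    t_end_s=t0_s + c / fs,
                    peak_to_peak_uv=pp,
                    channel=name,
                )
            )
            last_end = c
    return events


def detect_kcomplexes(sig: SignalRecord, params: KCParams = KCParams()) -> List[KComplexEvent]:
    """Detect K-complexes on the frontal derivations.

    Candidates are troughs below ``-amp_neg_uv`` in the 0.3–6 Hz band whose
    rebound carries a positive component; boundaries sit at the surrounding
    baseline crossings.  Events overlapping across F3/F4 are merged with the
    earliest start winning.
    """
    all_events: List[KComplexEvent] = []
    for name in sig.role_channels(FRONTAL):
        all_events.extend(
            _detect_kc_channel(sig.channels[name], sig.fs_hz, params, name, sig.t0_s)
        )
    all_events.sort(key=lambda e: (e.t_start_s, e.t_end_s))
    merged: List[KComplexEvent] = []
    for ev in all_events:
        if merged and ev.t_start_s < merged[-1].t_end_s:
            continue  # overlapping duplicate from the other derivation
        merged.append(ev)
    return merged


def first_kc_latency(events: Sequence[KComplexEvent]) -> Optional[float]:
    """Latency of the earliest K-complex in minutes from the anchor (None if none)."""
    if not events:
        return None
    return min(e.t_start_s for e in events) / 60.0


# ---------------------------------------------------------------------------
# REM arousals
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def _stage_at(hyp: Hypnogram, t_s: float) -> Optional[Stage]:
    i = int(np.floor(t_s / hyp.epoch_len_s))
    if 0 <= i < len(hyp.epochs):
        return hyp.epochs[i]
    return None


def detect_rem_arousals(
    sig: SignalRecord,
    hyp: Hypnogram,
    params: ArousalParams = ArousalParams(),
) -> List[ArousalEvent]:
    """Detect EMG-confirmed arousals within REM epochs.

    A candidate is a run where the summed envelope power of the shift bands
    exceeds ``power_factor`` times its segment median for ≥ ``min_shift_s``
    seconds, starting inside a REM epoch.  It becomes an event when chin-EMG
    amplitude exceeds ``emg_factor`` times its segment baseline for
    ≥ ``min_emg_s`` s within the run, and the preceding ``stable_s`` seconds
    are sleep (non-wake epochs), inside the record's coverage, and free of
    another detected arousal.
    """
    if not any(s is Stage.REM for s in hyp.epochs):
        warnings.warn("hypnogram contains no REM epochs; no arousals scored", stacklevel=2)
        return []
    try:
        eeg_names = sig.role_channels(OCCIPITAL)
    except RoleError:
        eeg_names = sig.role_channels(FRONTAL)
    emg_names = sig.role_channels(CHIN_EMG)

    fs = sig.fs_hz
    n = sig.n_samples
    smooth_n = max(1, int(round(params.smooth_s * fs)))

    power = np.zeros(n)
    for name in eeg_names:
        x = sig.channels[name]
        for lo, hi in params.shift_bands_hz:
            power += _envelope(_bandpass(x, fs, lo, hi)) ** 2
    power = _moving_average(power, smooth_n)

    emg = np.zeros(n)
    for name in emg_names:
        e = sps.sosfiltfilt(
            sps.butter(4, params.emg_highpass_hz, btype="highpass", fs=fs, output="sos"),
            sig.channels[name],
        )
        emg += _moving_average(np.abs(e), smooth_n)

    # sample-wise REM membership from the hypnogram
    t = sig.t0_s + np.arange(n) / fs
    epoch_idx = np.floor(t / hyp.epoch_len_s).astype(int)
    valid = (epoch_idx >= 0) & (epoch_idx < len(hyp.epochs))
    stage_arr = np.array([s.value for s in hyp.epochs], dtype=object)
    in_rem = np.zeros(n, dtype=bool)
    in_rem[valid] = stage_arr[epoch_idx[valid]] == Stage.REM.value

    if not in_rem.any():
        return []

    power_base = float(np.median(power[in_rem]))
    emg_base = float(np.median(emg[in_rem]))
    shift_mask = power > params.power_factor * power_base
    emg_mask = emg > params.emg_factor * emg_base

    events: List[ArousalEvent] = []
    min_shift_n = int(round(params.min_shift_s * fs))
    min_emg_n = int(round(params.min_emg_s * fs))
    for a, b in _runs(shift_mask):
        if b - a < min_shift_n:
            continue
        t_start = sig.t0_s + a / fs
        t_end = sig.t0_s + b / fs
        if not in_rem[a]:
            continue
        # EMG confirmation inside the run
        emg_ok = any(rb - ra >= min_emg_n for ra, rb in _runs(emg_mask[a:b]))
        if not emg_ok:
            continue
        # preceding stability: stable_s seconds of sleep within coverage,
        # free of wake epochs and of previously accepted arousals
        pre_start = t_start - params.stable_s
        if pre_start < sig.t0_s - 1e-9:
            continue
        stages_pre = {
            _stage_at(hyp, ts)
            for ts in np.arange(pre_start, t_start, hyp.epoch_len_s / 2.0)
        }
        stages_pre.add(_stage_at(hyp, t_start - 1e-6))
        if None in stages_pre or Stage.W in stages_pre:
            continue
        if any(ev.t_end_s > pre_start for ev in events):
            continue
        events.append(
            ArousalEvent(
                t_start_s=t_start,
                t_end_s=t_end,
                stage_context=Stage.REM,
                emg_confirmed=True,
            )
        )
    return events


def rem_arousal_density(
    events: Sequence[ArousalEvent], hyp: Hypnogram
) -> Optional[float]:
    """REM arousal density: fraction of REM epochs containing ≥ 1 arousal onset."""
    rem_epochs = [i for i, s in enumerate(hyp.epochs) if s is Stage.REM]
    if not rem_epochs:
        warnings.warn("hypnogram contains no REM epochs; A-REMd undefined", stacklevel=2)
        return None
    rem_set = set(rem_epochs)
    hit = set()
    for ev in events:
        i = int(np.floor(ev.t_start_s / hyp.epoch_len_s))
        if i in rem_set:
            hit.add(i)
    return len(hit) / len(rem_epochs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_signal_csv(sig: SignalRecord, path_or_buf, float_format: str = "%.3f") -> None:
    """Write a signal record as CSV with ``#`` metadata lines (fs, t0, roles)."""
    roles = ";".join(f"{role}:{','.join(names)}" for role, names in sorted(sig.roles.items()))
    header = f"# fs_hz={sig.fs_hz:g}\n# t0_s={sig.t0_s:g}\n# roles={roles}\n"
    df = pd.DataFrame(sig.channels)
    body = df.to_csv(index=False, float_format=float_format)
    text = header + body
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "wt", encoding="utf-8") as fh:
            fh.write(text)


def read_signal_csv(path_or_buf) -> SignalRecord:
    """Read a signal record written by :func:`write_signal_csv`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "rt", encoding="utf-8") as fh:
            text = fh.read()
    fs, t0, roles = None, 0.0, {}
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            item = line[1:].strip()
            if item.startswith("fs_hz="):
                fs = float(item.split("=", 1)[1])
            elif item.startswith("t0_s="):
                t0 = float(item.split("=", 1)[1])
            elif item.startswith("roles="):
                for part in item.split("=", 1)[1].split(";"):
                    if part:
                        role, names = part.split(":")
                        roles[role] = names.split(",")
        elif line.strip():
            body.append(line)
    if fs is None:
        raise StructureError("signal CSV missing '# fs_hz=' metadata line")
    df = pd.read_csv(io.StringIO("\n".join(body)))
    return SignalRecord(
        channels={c: df[c].to_numpy(dtype=float) for c in df.columns},
        fs_hz=fs,
        roles=roles,
        t0_s=t0,
    )


def read_signal_edf(path, roles: Mapping[str, Sequence[str]], t0_s: float = 0.0) -> SignalRecord:
    """Read an EDF recording into a :class:`SignalRecord` (requires ``mne``).

    ``roles`` maps roles to the EDF channel names to load, e.g.
    ``{"occipital": ["O1", "O2"], "frontal": ["F3", "F4"], "chin_emg": ["Chin1-Chin2"]}``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    wanted = [name for names in roles.values() for name in names]
    raw = mne.io.read_raw_edf(path, include=wanted, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    return SignalRecord(
        channels=channels,
        fs_hz=float(raw.info["sfreq"]),
        roles={role: list(names) for role, names in roles.items()},
        t0_s=t0_s,
    )


def events_to_frame(
    kcs: Sequence[KComplexEvent] = (), arousals: Sequence[ArousalEvent] = ()
) -> pd.DataFrame:
    """Long-format event table (CSV-ready) combining both event types."""
    rows = []
    for e in kcs:
        rows.append(
            {
                "type": "kcomplex",
                "t_start_s": e.t_start_s,
                "t_end_s": e.t_end_s,
                "channel": e.channel,
                "peak_to_peak_uv": e.peak_to_peak_uv,
                "emg_confirmed": None,
            }
        )
    for e in arousals:
        rows.append(
            {
                "type": "rem_arousal",
                "t_start_s": e.t_start_s,
                "t_end_s": e.t_end_s,
                "channel": None,
                "peak_to_peak_uv": None,
                "emg_confirmed": e.emg_confirmed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["type", "t_start_s", "t_end_s", "channel", "peak_to_peak_uv", "emg_confirmed"],
    )
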