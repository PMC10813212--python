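"""Scored hypnograms and objective sleep parameters.

A hypnogram is the ordered sequence of 30-s epoch sleep-stage labels
(W, N1, N2, N3, REM) produced by standard visual sleep scoring.  All latency,
total-sleep-time and transition computations in this package are driven by
this structure.  Timing convention: epoch ``i`` covers the half-open interval
``[i*epoch_len_s, (i+1)*epoch_len_s)`` seconds from the anchor (bedtime /
lights-off), so latencies are reported at epoch-start resolution.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParseError, StructureError, ValidationError

__all__ = [
    "Stage",
    "STAGE_ORDER",
    "SLEEP_STAGES",
    "Anchor",
    "Hypnogram",
    "ObjectiveSleepParams",
    "LatencySet",
    "parse_hypnogram",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "objective_sleep_params",
    "stage_latency",
    "restrict_window",
]


class Stage(str, Enum):
    """Closed set of sleep-stage labels used by AASM-style 30-s scoring."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    REM = "REM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical stage ordering used for transition matrices and reports.
STAGE_ORDER: Tuple[Stage, ...] = (Stage.W, Stage.N1, Stage.N2, Stage.N3, Stage.REM)

#: Sleep (non-wake) stages, in canonical order.
SLEEP_STAGES: Tuple[Stage, ...] = (Stage.N1, Stage.N2, Stage.N3, Stage.REM)


def _coerce_stage(token: object, row: Optional[object] = None) -> Stage:
    if isinstance(token, Stage):
        return token
    try:
        return Stage(str(token).strip())
    except ValueError:
        where = "" if row is None else f" (row {row})"
        raise ParseError(
            f"unknown stage token {token!r}{where}; expected one of "
            f"{[s.value for s in STAGE_ORDER]}"
        ) from None


@dataclass(frozen=True)
class Anchor:
    """Named time origin of a hypnogram.

    ``kind`` is ``"BEDTIME"`` (diary BT / lights-off moment) or
    ``"LIGHTS_OFF"``; ``clock`` is an optional "HH:MM" wall-clock time kept
    only for provenance — all analysis times are minutes from the anchor.
    """

    kind: str = "BEDTIME"
    clock: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("BEDTIME", "LIGHTS_OFF"):
            raise ValidationError(f"anchor kind must be BEDTIME or LIGHTS_OFF, got {self.kind!r}")


@dataclass(frozen=True)
class Hypnogram:
    """Validated sequence of epoch stage labels with a time anchor."""

    epochs: Tuple[Stage, ...]
    epoch_len_s: float = 30.0
    anchor: Anchor = field(default_factory=Anchor)

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise StructureError("hypnogram must contain at least one epoch")
        if not self.epoch_len_s > 0:
            raise ValidationError(f"epoch_len_s must be > 0, got {self.epoch_len_s}")
        coerced = tuple(_coerce_stage(s, i) for i, s in enumerate(self.epochs))
        object.__setattr__(self, "epochs", coerced)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def duration_min(self) -> float:
        """Total recording duration in minutes."""
        return len(self.epochs) * self.epoch_len_s / 60.0

    def epoch_start_min(self, i: int) -> float:
        """Start time of epoch ``i`` in minutes from the anchor."""
        return i * self.epoch_len_s / 60.0

    def labels(self) -> np.ndarray:
        """Stage labels as an object array of strings."""
        return np.array([s.value for s in self.epochs], dtype=object)


@dataclass(frozen=True)
class ObjectiveSleepParams:
    """PSG-derived sleep parameters for one night.

    ``sl_obj_min`` is the latency from the anchor to the first non-wake epoch
    (``None`` when no sleep occurred); ``stage_pct`` maps each sleep stage to
    its fraction of total sleep time (fractions, not percentages).
    """

    sl_obj_min: Optional[float]
    tst_obj_min: float
    waso_obj_min: float
    nawk_obj: int
    stage_pct: Mapping[Stage, float]

    def __post_init__(self) -> None:
        if self.tst_obj_min < 0 or self.waso_obj_min < 0 or self.nawk_obj < 0:
            raise ValidationError("objective sleep parameters must be non-negative")
        if self.tst_obj_min > 0:
            total = sum(self.stage_pct.get(s, 0.0) for s in SLEEP_STAGES)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"stage percentages must sum to 1, got {total}")


@dataclass(frozen=True)
class LatencySet:
    """Latency-to-stage measures in minutes from the anchor.

    Holds the latency to the first N1 epoch, the first N3 epoch and the first
    K-complex; each may be ``None`` when the feature never occurred.
    """

    lat_n1_min: Optional[float]
    lat_n3_min: Optional[float]
    lat_first_kc_min: Optional[float]

    def __post_init__(self) -> None:
        for name in ("lat_n1_min", "lat_n3_min", "lat_first_kc_min"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0 when present, got {v}")


RowsLike = Union[pd.DataFrame, Iterable[Tuple[object, object]]]


def parse_hypnogram(
    rows: RowsLike,
    epoch_len_s: float = 30.0,
    anchor: Optional[Anchor] = None,
    unscored_token: Optional[str] = None,
) -> Hypnogram:
    """Build a validated :class:`Hypnogram` from (epoch_index, stage) records.

    Parameters
    ----------
    rows
        DataFrame with columns ``epoch_index, stage`` or an iterable of
        ``(epoch_index, stage)`` pairs.  Indices must be contiguous from 0.
    unscored_token
        Optional token whose epochs are *dropped from the tail/head is not
        allowed*: an unscored epoch inside the record is a structure error,
        because every downstream computation assumes a gap-free grid.  Leading
        or trailing unscored epochs are trimmed with a warning.
    """
    if isinstance(rows, pd.DataFrame):
        if not {"epoch_index", "stage"}.issubset(rows.columns):
            raise StructureError("hypnogram table needs columns epoch_index, stage")
        pairs = list(zip(rows["epoch_index"].tolist(), rows["stage"].tolist()))
    else:
        pairs = [(i, s) for i, s in rows]
    if not pairs:
        raise StructureError("empty hypnogram record")

    indices = []
    for i, _ in pairs:
        try:
            indices.append(int(i))
        except (TypeError, ValueError):
            raise ParseError(f"non-integer epoch index {i!r}") from None
    expected = list(range(len(pairs)))
    if indices != expected:
        seen = set()
        for idx in indices:
            if idx in seen:
                raise StructureError(f"duplicate epoch index {idx}")
            seen.add(idx)
        missing = sorted(set(expected) - seen)
        raise StructureError(
            f"epoch indices must be contiguous from 0; missing {missing[:5]}"
        )

    tokens = [s for _, s in pairs]
    if unscored_token is not None:
        mask = [str(t).strip() == unscored_token for t in tokens]
        if any(mask):
            lo = next(i for i, m in enumerate(mask) if not m) if not all(mask) else None
            if lo is None:
                raise StructureError("all epochs unscored")
            hi = len(mask) - next(i for i, m in enumerate(reversed(mask)) if not m)
            if any(mask[lo:hi]):
                bad = lo + mask[lo:hi].index(True)
                raise StructureError(
                    f"unscored epoch {bad} inside the record; only leading/trailing "
                    "unscored epochs can be trimmed"
                )
            warnings.warn(
                f"trimmed {lo} leading and {len(mask) - hi} trailing unscored epochs",
                stacklevel=2,
            )
            tokens = tokens[lo:hi]

    stages = tuple(_coerce_stage(t, i) for i, t in enumerate(tokens))
    return Hypnogram(stages, epoch_len_s=epoch_len_s, anchor=anchor or Anchor())


def read_hypnogram_csv(path_or_buf, unscored_token: Optional[str] = None) -> Hypnogram:
    """Read a hypnogram CSV (``epoch_index,stage`` with ``#`` metadata lines)."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "rt", encoding="utf-8") as fh:
            text = fh.read()
    epoch_len_s = 30.0
    anchor_kind, anchor_clock = "BEDTIME", None
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            item = line[1:].strip()
            if item.startswith("epoch_len_s="):
                epoch_len_s = float(item.split("=", 1)[1])
            elif item.startswith("anchor="):
                parts = item.split("=", 1)[1].split()
                anchor_kind = parts[0]
                anchor_clock = parts[1] if len(parts) > 1 else None
        elif line.strip():
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)))
    return parse_hypnogram(
        df,
        epoch_len_s=epoch_len_s,
        anchor=Anchor(anchor_kind, anchor_clock),
        unscored_token=unscored_token,
    )


def write_hypnogram_csv(hyp: Hypnogram, path_or_buf) -> None:
    """Write a hypnogram in the round-trippable CSV format."""
    lines = [f"# epoch_len_s={hyp.epoch_len_s:g}"]
    anchor = hyp.anchor.kind if hyp.anchor.clock is None else f"{hyp.anchor.kind} {hyp.anchor.clock}"
    lines.append(f"# anchor={anchor}")
    lines.append("epoch_index,stage")
    lines.extend(f"{i},{s.value}" for i, s in enumerate(hyp.epochs))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "wt", encoding="utf-8") as fh:
            fh.write(text)


def objective_sleep_params(
    hyp: Hypnogram, waso_to_end_of_recording: bool = False
) -> ObjectiveSleepParams:
    """Compute SL, TST, WASO, awakening count and stage percentages.

    WASO counts wake epochs strictly between the first and last sleep epoch
    (the common convention); set ``waso_to_end_of_recording`` to extend the
    span to the end of the recording.  ``nawk_obj`` is the number of maximal
    wake runs inside the WASO span.
    """
    labels = hyp.labels()
    is_sleep = labels != Stage.W.value
    epm = hyp.epoch_len_s / 60.0

    if not is_sleep.any():
        warnings.warn("all-wake hypnogram: no sleep onset", stacklevel=2)
        return ObjectiveSleepParams(None, 0.0, 0.0, 0, {})

    first = int(np.argmax(is_sleep))
    last = int(len(labels) - 1 - np.argmax(is_sleep[::-1]))
    sl_obj = first * epm
    tst_obj = float(is_sleep.sum()) * epm

    span_end = len(labels) if waso_to_end_of_recording else last + 1
    wake_span = ~is_sleep[first:span_end]
    waso_obj = float(wake_span.sum()) * epm
    # count maximal wake runs within the span
    padded = np.concatenate(([False], wake_span))
    nawk = int(np.sum(padded[1:] & ~padded[:-1]))

    n_sleep = is_sleep.sum()
    stage_pct = {s: float(np.sum(labels == s.value)) / n_sleep for s in SLEEP_STAGES}
    return ObjectiveSleepParams(sl_obj, tst_obj, waso_obj, nawk, stage_pct)


def stage_latency(hyp: Hypnogram, target: Stage) -> Optional[float]:
    """Minutes from the anchor to the first epoch scored as ``target``.

    Returns ``None`` when the stage is never reached.
    """
    target = _coerce_stage(target)
    for i, s in enumerate(hyp.epochs):
        if s is target:
            return hyp.epoch_start_min(i)
    return None


def restrict_window(hyp: Hypnogram, start_min: float, end_min: float) -> Hypnogram:
    """Epochs whose start time falls in the half-open window ``[start, end)`` minutes.

    A window extending past the recording end is truncated with a warning; a
    window containing no epoch start is a structure error.
    """
    if not (0 <= start_min < end_min):
        raise ValidationError(
            f"window must satisfy 0 <= start < end, got [{start_min}, {end_min})"
        )
    if end_min > hyp.duration_min:
        warnings.warn(
            f"window end {end_min:g} min exceeds recording ({hyp.duration_min:g} min); truncated",
            stacklevel=2,
        )
    epm = hyp.epoch_len_s / 60.0
    lo = int(np.ceil(start_min / epm - 1e-12))
    hi = int(np.ceil(end_min / epm - 1e-12))
    hi = min(hi, len(hyp.epochs))
    if hi <= lo:
        raise StructureError(f"window [{start_min}, {end_min}) min contains no epoch")
    return Hypnogram(hyp.epochs[lo:hi], epoch_len_s=hyp.epoch_len_s, anchor=hyp.anchor)
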