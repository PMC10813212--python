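"""Subjective sleep-diary records.

One diary record per subject-night carries the self-reported counterparts of
the PSG parameters: bedtime (BT), subjective sleep latency, subjective total
sleep time, subjective wake-after-sleep-onset, and number of recalled
awakenings.  Clock arithmetic crosses midnight; every derived quantity used
downstream is a duration in minutes from BT, so wall-clock ambiguity never
propagates.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = ["SleepDiary", "parse_diary", "read_diaries_json", "read_diaries_csv"]

_REQUIRED = ("bt", "sl_subj_min", "tst_subj_min")
_DURATION_FIELDS = ("sl_subj_min", "tst_subj_min", "waso_subj_min")


def _parse_clock(value: object, fieldname: str) -> str:
    """Validate and normalise an ``HH:MM`` clock string."""
    s = str(value).strip()
    parts = s.split(":")
    try:
        h, m = int(parts[0]), int(parts[1])
    except (IndexError, ValueError):
        raise ParseError(f"field {fieldname!r}: cannot parse clock time {value!r}") from None
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ParseError(f"field {fieldname!r}: clock time {value!r} out of range")
    return f"{h:02d}:{m:02d}"


def _clock_to_min(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


def _min_to_clock(total: float) -> str:
    total = int(round(total)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


def add_minutes(clock: str, minutes: float) -> str:
    """Clock time ``minutes`` after ``clock``, wrapping past midnight."""
    return _min_to_clock(_clock_to_min(clock) + minutes)


def minutes_between(start_clock: str, end_clock: str) -> float:
    """Minutes from ``start_clock`` forward to the next occurrence of ``end_clock``."""
    delta = _clock_to_min(end_clock) - _clock_to_min(start_clock)
    return float(delta % (24 * 60))


@dataclass(frozen=True)
class SleepDiary:
    """Validated subjective sleep parameters for one night."""

    subject_id: str
    bt_clock: str
    sl_subj_min: float
    tst_subj_min: float
    waso_subj_min: Optional[float] = None
    nawk_subj: Optional[int] = None
    final_wake_clock: Optional[str] = None
    out_of_bed_clock: Optional[str] = None
    completed_within_min: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _DURATION_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"field {name!r}: negative duration {v}")
        if self.nawk_subj is not None and (self.nawk_subj < 0 or self.nawk_subj != int(self.nawk_subj)):
            raise ValidationError(f"field 'nawk_subj': must be a non-negative integer, got {self.nawk_subj}")

    @property
    def so_subj_clock(self) -> str:
        """Subjective sleep-onset clock time, BT + subjective sleep latency."""
        return add_minutes(self.bt_clock, self.sl_subj_min)

    @property
    def time_in_bed_min(self) -> Optional[float]:
        """Minutes from BT to out-of-bed time, when the latter was reported."""
        if self.out_of_bed_clock is None:
            return None
        return minutes_between(self.bt_clock, self.out_of_bed_clock)


def _is_missing(v: object) -> bool:
    return v is None or v == "" or (isinstance(v, float) and pd.isna(v))


def _opt_float(record: Mapping, key: str) -> Optional[float]:
    v = record.get(key)
    if _is_missing(v):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ParseError(f"field {key!r}: cannot parse number {v!r}") from None


def parse_diary(record: Mapping) -> SleepDiary:
    """Build a validated :class:`SleepDiary` from a keyed record.

    Required keys: ``bt``, ``sl_subj_min``, ``tst_subj_min``.  A reported TST
    equalling or exceeding the time in bed (when out-of-bed time is present)
    is physiologically suspicious and produces a warning, not an error.
    """
    for key in _REQUIRED:
        if _is_missing(record.get(key)):
            raise ParseError(f"field {key!r}: required key missing")
    bt = _parse_clock(record["bt"], "bt")
    sl = _opt_float(record, "sl_subj_min")
    tst = _opt_float(record, "tst_subj_min")
    nawk_raw = _opt_float(record, "nawk_subj")
    diary = SleepDiary(
        subject_id=str(record.get("subject_id", "")),
        bt_clock=bt,
        sl_subj_min=sl,
        tst_subj_min=tst,
        waso_subj_min=_opt_float(record, "waso_subj_min"),
        nawk_subj=None if nawk_raw is None else int(nawk_raw),
        final_wake_clock=(
            None if _is_missing(record.get("final_wake"))
            else _parse_clock(record["final_wake"], "final_wake")
        ),
        out_of_bed_clock=(
            None if _is_missing(record.get("out_of_bed"))
            else _parse_clock(record["out_of_bed"], "out_of_bed")
        ),
        completed_within_min=_opt_float(record, "completed_within_min"),
    )
    tib = diary.time_in_bed_min
    if tib is not None and diary.tst_subj_min >= tib:
        warnings.warn(
            f"subject {diary.subject_id!r}: reported TST ({diary.tst_subj_min:g} min) "
            f">= time in bed ({tib:g} min)",
            stacklevel=2,
        )
    return diary


def read_diaries_json(path_or_buf) -> list[SleepDiary]:
    """Read a JSON array of diary objects (one per subject-night)."""
    if hasattr(path_or_buf, "read"):
        records = json.load(path_or_buf)
    else:
        with open(path_or_buf, "rt", encoding="utf-8") as fh:
            records = json.load(fh)
    return [parse_diary(r) for r in records]


def read_diaries_csv(path_or_buf) -> list[SleepDiary]:
    """Read diaries from CSV with the same column names as the JSON keys."""
    df = pd.read_csv(path_or_buf)
    return [parse_diary(row.to_dict()) for _, row in df.iterrows()]
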