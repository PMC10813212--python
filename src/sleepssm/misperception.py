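"""Sleep-state misperception indices.

Misperception is quantified as the ratio of the subjective to the objective
estimate of a sleep parameter, expressed as a percentage:

* ``SLm  = (SL_subj  / SL_obj)  x 100`` — values above 100% mean the sleep
  latency was overestimated;
* ``TSTm = (TST_subj / TST_obj) x 100`` — values below 100% mean total sleep
  time was underestimated.

The raw latency discrepancy ``SL_subj - SL_obj`` (minutes) splits a cohort
into lower- and higher-discrepancy subgroups at a 10-minute cutoff, the
shortest uninterrupted sleep period reliably recognised as sleep.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import UndefinedIndexError, ValidationError

__all__ = [
    "MisperceptionIndices",
    "sl_misperception",
    "tst_misperception",
    "compute_indices",
    "split_by_discrepancy",
    "indices_to_frame",
]

DEFAULT_CUTOFF_MIN = 10.0

LOW = "LOW"
HIGH = "HIGH"


@dataclass(frozen=True)
class MisperceptionIndices:
    """Per-subject misperception summary.

    ``slm_pct`` is ``None`` when SL_obj was zero (subject slept at the first
    epoch; the ratio is undefined and the subject is excluded from SLm
    analyses).
    """

    subject_id: str
    slm_pct: Optional[float]
    tstm_pct: float
    sl_discrepancy_min: float
    discrepancy_group: str

    def __post_init__(self) -> None:
        if self.discrepancy_group not in (LOW, HIGH):
            raise ValidationError(f"discrepancy_group must be LOW or HIGH, got {self.discrepancy_group!r}")


def sl_misperception(sl_subj_min: float, sl_obj_min: float) -> float:
    """Sleep-latency misperception index ``(SL_subj / SL_obj) x 100``."""
    if sl_obj_min <= 0:
        raise UndefinedIndexError(
            f"SLm undefined: objective sleep latency is {sl_obj_min} min"
        )
    if sl_subj_min < 0:
        raise ValidationError(f"subjective sleep latency must be >= 0, got {sl_subj_min}")
    return sl_subj_min / sl_obj_min * 100.0


def tst_misperception(tst_subj_min: float, tst_obj_min: float) -> float:
    """Total-sleep-time misperception index ``(TST_subj / TST_obj) x 100``."""
    if tst_obj_min <= 0:
        raise UndefinedIndexError(
            f"TSTm undefined: objective total sleep time is {tst_obj_min} min"
        )
    if tst_subj_min < 0:
        raise ValidationError(f"subjective TST must be >= 0, got {tst_subj_min}")
    return tst_subj_min / tst_obj_min * 100.0


def classify_discrepancy(
    sl_discrepancy_min: float, cutoff_min: float = DEFAULT_CUTOFF_MIN, ties_to: str = LOW
) -> str:
    """Group label for a raw SL discrepancy; a tie at the cutoff goes to ``ties_to``."""
    if cutoff_min <= 0:
        raise ValidationError(f"cutoff must be > 0, got {cutoff_min}")
    if sl_discrepancy_min > cutoff_min:
        return HIGH
    if sl_discrepancy_min < cutoff_min:
        return LOW
    return ties_to


def compute_indices(
    subject_id: str,
    sl_subj_min: float,
    sl_obj_min: Optional[float],
    tst_subj_min: float,
    tst_obj_min: float,
    cutoff_min: float = DEFAULT_CUTOFF_MIN,
    ties_to: str = LOW,
) -> MisperceptionIndices:
    """All misperception indices for one subject.

    An SL_obj of zero (or ``None``) leaves SLm undefined with a logged
    warning; the discrepancy and group are then computed with SL_obj = 0.
    """
    if sl_obj_min is None or sl_obj_min <= 0:
        warnings.warn(
            f"subject {subject_id!r}: SL_obj={sl_obj_min}; SLm undefined, "
            "subject excluded from SLm analyses",
            stacklevel=2,
        )
        slm = None
        disc = sl_subj_min - (sl_obj_min or 0.0)
    else:
        slm = sl_misperception(sl_subj_min, sl_obj_min)
        disc = sl_subj_min - sl_obj_min
    return MisperceptionIndices(
        subject_id=subject_id,
        slm_pct=slm,
        tstm_pct=tst_misperception(tst_subj_min, tst_obj_min),
        sl_discrepancy_min=disc,
        discrepancy_group=classify_discrepancy(disc, cutoff_min, ties_to),
    )


def split_by_discrepancy(
    subjects: Iterable[Tuple[str, float, float]],
    cutoff_min: float = DEFAULT_CUTOFF_MIN,
    ties_to: str = LOW,
) -> Tuple[List[str], List[str]]:
    """Partition ``(id, sl_subj, sl_obj)`` triples into (LOW, HIGH) id lists."""
    low, high = [], []
    for sid, sl_subj, sl_obj in subjects:
        group = classify_discrepancy(sl_subj - sl_obj, cutoff_min, ties_to)
        (high if group == HIGH else low).append(sid)
    return low, high


def indices_to_frame(indices: Sequence[MisperceptionIndices]) -> pd.DataFrame:
    """Tabulate per-subject indices (full precision; round only at report time)."""
    return pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in indices],
            "slm_pct": [m.slm_pct for m in indices],
            "tstm_pct": [m.tstm_pct for m in indices],
            "sl_discrepancy_min": [m.sl_discrepancy_min for m in indices],
            "discrepancy_group": [m.discrepancy_group for m in indices],
        }
    )
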