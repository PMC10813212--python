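"""First-order Markov analysis of stage transitions in the sleep-onset window.

Per subject, the stage sequence inside the *subjective* sleep-latency window
(bedtime to reported sleep onset) is summarised as a 5x5 transition-count
matrix over {W, N1, N2, N3, REM} and normalised row-wise into
maximum-likelihood transition probabilities.  A from-stage never visited in
the window yields a *missing* row (NaN), never a zero-filled one: "never left
N1" and "never reached N1" are different facts, and group comparisons must
not conflate them.  Specific transition probabilities (canonically N1→W) are
compared between discrepancy groups with the Mann-Whitney U test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diary import SleepDiary
from .errors import ComparisonError, StructureError, ValidationError
from .hypnogram import STAGE_ORDER, Hypnogram, Stage, restrict_window
from .stats import RankTestResult, mann_whitney

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "TransitionComparison",
    "transition_counts",
    "transition_matrix",
    "subjective_sl_matrix",
    "compare_transition",
    "matrices_to_frame",
]

_INDEX = {s: i for i, s in enumerate(STAGE_ORDER)}


@dataclass(frozen=True)
class TransitionCounts:
    """Integer transition counts indexed (from-stage, to-stage) in canonical order."""

    counts: np.ndarray
    n_transitions: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (5, 5) or (c < 0).any():
            raise ValidationError("counts must be a non-negative 5x5 matrix")
        if int(c.sum()) != self.n_transitions:
            raise ValidationError("n_transitions must equal the sum of counts")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic MLE transition probabilities with per-row visit counts.

    Rows of never-visited from-stages are NaN and flagged by ``row_visits == 0``.
    """

    probs: np.ndarray
    row_visits: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        v = np.asarray(self.row_visits)
        if p.shape != (5, 5) or v.shape != (5,):
            raise ValidationError("probs must be 5x5 and row_visits length 5")
        for i in range(5):
            if v[i] == 0:
                if not np.isnan(p[i]).all():
                    raise ValidationError(f"row {STAGE_ORDER[i].value} unvisited but not NaN")
            else:
                if abs(p[i].sum() - 1.0) > 1e-12:
                    raise ValidationError(
                        f"row {STAGE_ORDER[i].value} sums to {p[i].sum()!r}, expected 1"
                    )

    def prob(self, frm: Stage, to: Stage) -> float:
        """P(frm -> to); NaN when the from-stage was never visited."""
        return float(self.probs[_INDEX[frm], _INDEX[to]])

    def is_missing(self, frm: Stage) -> bool:
        return int(self.row_visits[_INDEX[frm]]) == 0


@dataclass(frozen=True)
class TransitionComparison:
    """Between-group comparison of one transition probability."""

    frm: Stage
    to: Stage
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    n_excluded_a: int
    n_excluded_b: int
    test: RankTestResult


def transition_counts(seq: Sequence[Stage]) -> TransitionCounts:
    """Count consecutive stage pairs (self-transitions included)."""
    if len(seq) < 2:
        raise StructureError(f"need at least 2 epochs to count transitions, got {len(seq)}")
    counts = np.zeros((5, 5), dtype=int)
    for a, b in zip(seq[:-1], seq[1:]):
        counts[_INDEX[Stage(a)], _INDEX[Stage(b)]] += 1
    return TransitionCounts(counts=counts, n_transitions=len(seq) - 1)


def transition_matrix(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalise counts into MLE probabilities; unvisited rows become NaN."""
    c = np.asarray(counts.counts, dtype=float)
    row_visits = c.sum(axis=1).astype(int)
    probs = np.full((5, 5), np.nan)
    for i in range(5):
        if row_visits[i] > 0:
            probs[i] = c[i] / row_visits[i]
    return TransitionMatrix(probs=probs, row_visits=row_visits)


def subjective_sl_matrix(hyp: Hypnogram, diary: SleepDiary) -> Optional[TransitionMatrix]:
    """Transition matrix of the hypnogram restricted to [0, SL_subj) minutes.

    Returns ``None`` with a warning when the subjective latency window holds
    fewer than two epochs (no transition can be observed).
    """
    n_window = int(np.floor(diary.sl_subj_min * 60.0 / hyp.epoch_len_s + 1e-9))
    if n_window < 2:
        warnings.warn(
            f"subject {diary.subject_id!r}: subjective SL window of "
            f"{diary.sl_subj_min:g} min holds < 2 epochs; matrix missing",
            stacklevel=2,
        )
        return None
    window = restrict_window(hyp, 0.0, diary.sl_subj_min)
    if len(window) < 2:
        warnings.warn(
            f"subject {diary.subject_id!r}: window truncated below 2 epochs; matrix missing",
            stacklevel=2,
        )
        return None
    return transition_matrix(transition_counts(window.epochs))


def _extract(group: Sequence[TransitionMatrix], frm: Stage, to: Stage) -> Tuple[List[float], int]:
    values, excluded = [], 0
    for tm in group:
        if tm is None or tm.is_missing(frm):
            excluded += 1
        else:
            values.append(tm.prob(frm, to))
    return values, excluded


def compare_transition(
    group_a: Sequence[TransitionMatrix],
    group_b: Sequence[TransitionMatrix],
    frm: Stage,
    to: Stage,
) -> TransitionComparison:
    """Mann-Whitney comparison of P(frm→to) between two groups of matrices.

    Subjects whose from-stage row is missing are excluded with counts
    reported.  Group A is the first sample of the rank test, so the
    rank-biserial sign follows the (A, B) order given here.
    """
    vals_a, excl_a = _extract(group_a, frm, to)
    vals_b, excl_b = _extract(group_b, frm, to)
    for name, vals in (("A", vals_a), ("B", vals_b)):
        if not vals:
            raise ComparisonError(
                f"group {name}: no subject has a non-missing {frm.value}->{to.value} probability"
            )
    test = mann_whitney(vals_a, vals_b)
    return TransitionComparison(
        frm=frm,
        to=to,
        mean_a=float(np.mean(vals_a)),
        sd_a=float(np.std(vals_a, ddof=1)) if len(vals_a) > 1 else 0.0,
        mean_b=float(np.mean(vals_b)),
        sd_b=float(np.std(vals_b, ddof=1)) if len(vals_b) > 1 else 0.0,
        n_a=len(vals_a),
        n_b=len(vals_b),
        n_excluded_a=excl_a,
        n_excluded_b=excl_b,
        test=test,
    )


def matrices_to_frame(matrices: Sequence[Tuple[str, Optional[TransitionMatrix]]]) -> pd.DataFrame:
    """Long-format table ``subject_id, from, to, prob, row_visits, missing``."""
    rows = []
    for sid, tm in matrices:
        for i, frm in enumerate(STAGE_ORDER):
            for j, to in enumerate(STAGE_ORDER):
                if tm is None:
                    rows.append((sid, frm.value, to.value, np.nan, 0, True))
                else:
                    rows.append(
                        (
                            sid,
                            frm.value,
                            to.value,
                            tm.probs[i, j],
                            int(tm.row_visits[i]),
                            bool(tm.row_visits[i] == 0),
                        )
                    )
    return pd.DataFrame(rows, columns=["subject_id", "from", "to", "prob", "row_visits", "missing"])
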