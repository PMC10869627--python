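"""Scoring the monitoring policy against crises and latent states.

The unit of analysis is the patient-week: the confusion matrix crosses
"flagged for close monitoring" with "a crisis occurred that week", and
precision / recall (sensitivity) / specificity / false-positive rate /
F1 follow the standard definitions.  When simulation ground truth is
available, occupancy metrics ask how often flagged weeks, first
deemed-stable weeks after a crisis episode, and the four weeks after
them actually find the patient in the unstable state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .policy import ALWAYS, NEVER, MonitoringPlan

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "classification_metrics",
    "state_occupancy_metrics",
    "weeks_to_stable_distribution",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-week counts of flagged x crisis-occurred."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    """Aggregated policy scores; NaN marks undefined rates."""

    precision: float = np.nan
    recall: float = np.nan
    specificity: float = np.nan
    fpr: float = np.nan
    f1: float = np.nan
    mean_flagged_per_week: float = np.nan
    pct_flagged_per_week: float = np.nan
    pct_flagged_in_U: float = np.nan
    pct_U_at_stable_week: float = np.nan
    pct_U_following_weeks: float = np.nan
    weeks_to_stable_histogram: dict = field(default_factory=dict)


def _as_2d(a) -> np.ndarray:
    arr = np.asarray(a)
    return arr[None, :] if arr.ndim == 1 else arr


def confusion_matrix(flags, crises) -> ConfusionMatrix:
    """Cross-tabulate weekly flags against weekly crises.

    Accepts 1-D (one patient) or 2-D (patients x weeks) aligned arrays.
    """
    f = np.asarray(flags).astype(bool)
    y = np.asarray(crises).astype(bool)
    if f.shape != y.shape:
        raise ValueError(f"misaligned shapes {f.shape} vs {y.shape}")
    return ConfusionMatrix(
        tp=int(np.sum(f & y)),
        fp=int(np.sum(f & ~y)),
        fn=int(np.sum(~f & y)),
        tn=int(np.sum(~f & ~y)),
    )


def classification_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """Precision, recall, specificity, FPR and F1 from a confusion matrix.

    Rates with a zero denominator are NaN, with a warning.
    """
    rep = EvaluationReport()

    def rate(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return np.nan
        return num / den

    rep.precision = rate(cm.tp, cm.tp + cm.fp, "precision")
    rep.recall = rate(cm.tp, cm.tp + cm.fn, "recall")
    rep.specificity = rate(cm.tn, cm.tn + cm.fp, "specificity")
    rep.fpr = 1.0 - rep.specificity if np.isfinite(rep.specificity) else np.nan
    if np.isfinite(rep.precision) and np.isfinite(rep.recall):
        s = rep.precision + rep.recall
        rep.f1 = 2.0 * rep.precision * rep.recall / s if s > 0 else np.nan
    return rep


def _stable_week_indices(
    flags: np.ndarray, crises: np.ndarray
) -> list[tuple[int, int]]:
    """(patient, week) of the first unflagged week closing each episode.

    An episode opens at a crisis week; further crises before the policy
    stops flagging extend the same episode; the episode closes at the
    first subsequent unflagged week.  Episodes still open at the end of
    the window yield no stable week.
    """
    out: list[tuple[int, int]] = []
    n, T = flags.shape
    for i in range(n):
        in_episode = False
        for t in range(T):
            if in_episode and not flags[i, t]:
                out.append((i, t))
                in_episode = False
            if crises[i, t]:
                in_episode = True
    return out


def state_occupancy_metrics(
    flags, true_states, crises, following_weeks: int = 4
) -> dict[str, float]:
    """Latent-state occupancy of flagged and deemed-stable patient-weeks.

    Returns percentages (0-100): ``pct_flagged_in_U`` over all flagged
    weeks; ``pct_U_at_stable_week`` over the first unflagged week after
    each crisis episode; ``pct_U_following_weeks`` over the
    ``following_weeks`` weeks after those (within the window).  NaN when
    the relevant set of weeks is empty.
    """
    f = _as_2d(flags).astype(bool)
    st = _as_2d(true_states).astype(np.int8)
    cr = _as_2d(crises).astype(bool)
    if not (f.shape == st.shape == cr.shape):
        raise ValueError("flags, true_states and crises must align")
    n_flagged = int(f.sum())
    pct_flagged_in_U = (
        100.0 * float(st[f].mean()) if n_flagged else np.nan
    )
    stable = _stable_week_indices(f, cr)
    pct_stable_U = (
        100.0 * float(np.mean([st[i, t] for i, t in stable]))
        if stable else np.nan
    )
    following = [
        st[i, u]
        for i, t in stable
        for u in range(t + 1, min(t + 1 + following_weeks, st.shape[1]))
    ]
    pct_following_U = (
        100.0 * float(np.mean(following)) if following else np.nan
    )
    return {
        "pct_flagged_in_U": pct_flagged_in_U,
        "pct_U_at_stable_week": pct_stable_U,
        "pct_U_following_weeks": pct_following_U,
    }


def weeks_to_stable_distribution(
    plans: Sequence[MonitoringPlan] | Mapping[str, MonitoringPlan],
) -> dict[str, float]:
    """Fractions of patients per monitoring-duration bin.

    Bins are NEVER / "1" / "2" / "3+" / ALWAYS and the fractions sum to
    one.
    """
    values = (
        [p.weeks_to_stable for p in plans.values()]
        if isinstance(plans, Mapping)
        else [p.weeks_to_stable for p in plans]
    )
    if not values:
        raise ValueError("no monitoring plans given")
    n = len(values)
    hist = {NEVER: 0, "1": 0, "2": 0, "3+": 0, ALWAYS: 0}
    for w in values:
        if w in (ALWAYS, NEVER):
            hist[w] += 1
        elif w == 1:
            hist["1"] += 1
        elif w == 2:
            hist["2"] += 1
        else:
            hist["3+"] += 1
    return {k: v / n for k, v in hist.items()}
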