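"""Threshold-based close-monitoring policy.

A patient-week is flagged for close monitoring when the predicted crisis
risk exceeds a threshold tau (0.35 by default, the value that maximises
F1 in the cohort simulation).  The per-patient monitoring plan counts
how many crisis-free weeks after a crisis the risk stays above tau:
a finite number of weeks, ``ALWAYS`` (the asymptotic risk itself is at
or above tau) or ``NEVER`` (even the first post-crisis week is below).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import CrisisSeries
from .hmm_core import (
    ImpossibleObservationError,
    ModelParams,
    U,
    _filter_risk_batch,
    risk_curve,
    risk_limit,
)

__all__ = [
    "ALWAYS",
    "NEVER",
    "PolicyConfig",
    "MonitoringPlan",
    "weeks_to_stable",
    "run_policy",
    "threshold_sweep",
]

ALWAYS = "always"
NEVER = "never"


@dataclass(frozen=True)
class PolicyConfig:
    """Monitoring-policy settings.

    ``tau`` is the risk threshold; ``min_history_weeks`` the three-month
    rule below which pooled parameters are assigned; ``max_horizon``
    caps the weeks-to-stable search (the ALWAYS decision itself is
    horizon-free, via the closed-form risk limit).
    """

    tau: float = 0.35
    min_history_weeks: int = 13
    max_horizon: int = 104

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must be in (0, 1)")
        if self.max_horizon < 1:
            raise ValueError("max_horizon must be >= 1")


@dataclass(frozen=True)
class MonitoringPlan:
    """Close-monitoring duration after a crisis for one patient.

    ``weeks_to_stable`` is a positive integer k (risk above tau at some
    week <= k and below afterwards), ``ALWAYS`` or ``NEVER``.  The
    crisis week itself is not counted: a value of 1 means "monitor the
    week following the crisis, deem stable from the second week".
    """

    patient_id: str
    weeks_to_stable: int | str

    def __post_init__(self) -> None:
        w = self.weeks_to_stable
        if not (w in (ALWAYS, NEVER) or (isinstance(w, int) and w >= 1)):
            raise ValueError(f"invalid weeks_to_stable: {w!r}")


def weeks_to_stable(
    params: ModelParams,
    config: PolicyConfig = PolicyConfig(),
    patient_id: str = "",
) -> MonitoringPlan:
    """Monitoring duration implied by a patient's risk curve after a crisis.

    The risk curve is anchored at an observed crisis (state U at week 0).
    Because the curve need not be monotone for every parameter corner,
    the rule scans ``t = 1..max_horizon`` and returns the last week with
    risk above tau; no such week means ``NEVER``, and an asymptotic risk
    at or above tau means ``ALWAYS`` regardless of the horizon.
    """
    try:
        if risk_limit(params) >= config.tau:
            return MonitoringPlan(patient_id, ALWAYS)
        curve = risk_curve(params, U, 1, config.max_horizon)
    except ImpossibleObservationError:
        # p = r = 1 corner: a crisis-free week after a crisis has
        # probability zero, so the risk never falls below any threshold
        return MonitoringPlan(patient_id, ALWAYS)
    above = np.nonzero(curve.risk > config.tau)[0]
    if len(above) == 0:
        return MonitoringPlan(patient_id, NEVER)
    return MonitoringPlan(patient_id, int(above[-1]) + 1)


def _cohort_risks(
    cohort: Sequence[CrisisSeries],
    params_map: Mapping[str, ModelParams],
) -> np.ndarray:
    """(N, T) predictive risk for every patient-week from full history.

    Week 0 uses the stationary prior of each patient's chain (no anchor
    observed yet); afterwards the Bayes filter conditions on the full
    crisis history, so a crisis at week t resets the week t+1 risk to
    p*r.  All series must share a common length.
    """
    lengths = {len(s) for s in cohort}
    if len(lengths) != 1:
        raise ValueError("cohort series must share a common length")
    obs = np.vstack([s.obs for s in cohort])
    p = np.array([params_map[s.patient_id].p for s in cohort])
    q = np.array([params_map[s.patient_id].q for s in cohort])
    r = np.array([params_map[s.patient_id].r for s in cohort])
    prior = np.array(
        [params_map[s.patient_id].stationary_U for s in cohort]
    )
    return _filter_risk_batch(p, q, r, prior, obs)


def run_policy(
    cohort: Sequence[CrisisSeries],
    params_map: Mapping[str, ModelParams],
    config: PolicyConfig = PolicyConfig(),
    eval_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Weekly monitoring flags for a cohort.

    For each patient-week in ``eval_window`` (half-open ``[start, stop)``
    week-index range; defaults to the full series), the predicted risk is
    computed from the patient's full crisis history up to the previous
    week and the week is flagged when it exceeds tau.  Returns a tidy
    frame with columns patient_id, week, risk, flagged, crisis.
    """
    risks = _cohort_risks(cohort, params_map)
    T = risks.shape[1]
    start, stop = eval_window if eval_window is not None else (0, T)
    if not (0 <= start < stop <= T):
        raise ValueError(f"invalid eval_window {(start, stop)} for T={T}")
    weeks = np.arange(start, stop)
    frames = []
    for i, s in enumerate(cohort):
        frames.append(pd.DataFrame({
            "patient_id": s.patient_id,
            "week": weeks,
            "risk": risks[i, start:stop],
            "flagged": risks[i, start:stop] > config.tau,
            "crisis": s.obs[start:stop].astype(bool),
        }))
    return pd.concat(frames, ignore_index=True)


def threshold_sweep(
    cohort: Sequence[CrisisSeries],
    params_map: Mapping[str, ModelParams],
    taus: Sequence[float],
    eval_window: tuple[int, int] | None = None,
    labels: pd.Series | np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """F1 of the policy across a grid of thresholds.

    Risks are computed once; each tau is applied to the same risk table
    and scored against ``labels`` (default: the observed crises) over the
    evaluation window.  Returns the F1-maximising tau (ties resolved to
    the smallest) and the per-tau metric table.
    """
    taus = list(taus)
    if len(taus) == 0:
        raise ValueError("empty threshold grid")
    base = run_policy(cohort, params_map, PolicyConfig(tau=0.5),
                      eval_window=eval_window)
    y = (np.asarray(labels).astype(bool) if labels is not None
         else base["crisis"].to_numpy())
    risk = base["risk"].to_numpy()
    rows = []
    for tau in taus:
        flags = risk > tau
        tp = int(np.sum(flags & y))
        fp = int(np.sum(flags & ~y))
        fn = int(np.sum(~flags & y))
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if tp + fp and tp + fn and (prec + rec) else np.nan)
        rows.append({"tau": tau, "precision": prec, "recall": rec, "f1": f1})
    table = pd.DataFrame(rows)
    f1s = table["f1"].to_numpy()
    if np.all(np.isnan(f1s)):
        best = float(min(taus))
    else:
        best_f1 = np.nanmax(f1s)
        best = float(table.loc[
            np.isclose(f1s, best_f1, rtol=0, atol=0, equal_nan=False),
            "tau"
        ].min())
    return best, table
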