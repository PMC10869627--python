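"""Data ingestion, configuration and fixture generation.

Real crisis data arrive as dated event records (one row per crisis:
patient id + ISO-8601 event date).  The model works on weekly binary
sequences, so events are binned into 7-day weeks anchored either at each
patient's first record (the model's week 0 is patient-relative) or at a
global calendar origin, which is what train/eval date splits need.
Multiple crises within one week collapse to a single 1: the weekly
crisis indicator is binary.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import CrisisSeries, FitConfig, FitResult
from .hmm_core import ModelParams
from .policy import MonitoringPlan, PolicyConfig
from .cohort_sim import SimConfig

__all__ = [
    "CrisisEventRecord",
    "RunConfig",
    "read_events_csv",
    "write_events_csv",
    "events_to_weekly",
    "series_to_events",
    "write_weekly_csv",
    "read_weekly_csv",
    "write_params_csv",
    "read_params_csv",
    "write_plans_csv",
    "load_run_config",
    "make_fixtures",
]


@dataclass(frozen=True)
class CrisisEventRecord:
    """One recorded crisis: who and when."""

    patient_id: str
    event_date: dt.date

    def __post_init__(self) -> None:
        if not isinstance(self.event_date, dt.date):
            raise TypeError("event_date must be a datetime.date")


@dataclass(frozen=True)
class RunConfig:
    """Bundle of sub-configurations for a full pipeline run."""

    policy: PolicyConfig = PolicyConfig()
    fit: FitConfig = FitConfig()
    simulation: SimConfig = SimConfig()
    split_week: int | None = None
    paths: dict = field(default_factory=dict)


def read_events_csv(path: str | Path) -> list[CrisisEventRecord]:
    """Read a `patient_id,event_date` CSV of crisis events."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = {"patient_id", "event_date"} - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    try:
        dates = pd.to_datetime(df["event_date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable event_date: {exc}") from exc
    return [
        CrisisEventRecord(patient_id=pid, event_date=d.date())
        for pid, d in zip(df["patient_id"], dates)
    ]


def write_events_csv(
    records: Iterable[CrisisEventRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"patient_id": r.patient_id,
             "event_date": r.event_date.isoformat()}
            for r in records
        ]
    ).to_csv(path, index=False)


def events_to_weekly(
    records: Sequence[CrisisEventRecord],
    origin: str | dt.date = "first_event",
    end_date: dt.date | None = None,
) -> list[CrisisSeries]:
    """Bin dated crisis events into weekly 0/1 series, one per patient.

    ``origin`` is either ``"first_event"`` (week 0 starts at each
    patient's first recorded crisis) or a global calendar date shared by
    all patients.  Week ``t`` covers days ``[origin + 7t, origin + 7t+7)``.
    ``end_date`` optionally extends every series with crisis-free weeks
    up to (and including) the week containing that date.
    """
    if not records:
        raise ValueError("no event records given")
    by_patient: dict[str, list[dt.date]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r.event_date)
    out = []
    for pid in sorted(by_patient):
        dates = sorted(by_patient[pid])
        anchor = dates[0] if origin == "first_event" else origin
        if not isinstance(anchor, dt.date):
            raise ValueError(f"invalid origin {origin!r}")
        weeks = [(d - anchor).days // 7 for d in dates]
        if min(weeks) < 0:
            raise ValueError(
                f"event before origin {anchor} for patient {pid!r}"
            )
        last = max(weeks)
        if end_date is not None:
            last = max(last, (end_date - anchor).days // 7)
        obs = np.zeros(last + 1, dtype=np.int8)
        obs[weeks] = 1
        out.append(CrisisSeries(patient_id=pid, obs=obs, start_week=anchor))
    return out


def series_to_events(
    series: Sequence[CrisisSeries],
    default_origin: dt.date = dt.date(2012, 9, 3),
) -> list[CrisisEventRecord]:
    """Inverse of :func:`events_to_weekly` on the crisis weeks.

    Each crisis week emits one event dated at that week's first day,
    using the series' ``start_week`` anchor (or ``default_origin``).
    """
    out = []
    for s in series:
        anchor = s.start_week if isinstance(s.start_week, dt.date) \
            else default_origin
        for t in np.nonzero(s.obs)[0]:
            out.append(CrisisEventRecord(
                patient_id=s.patient_id,
                event_date=anchor + dt.timedelta(weeks=int(t)),
            ))
    return out


def write_weekly_csv(
    series: Sequence[CrisisSeries], path: str | Path
) -> None:
    """`patient_id,week_index,week_start,crisis` rows, one per week."""
    rows = []
    for s in series:
        for t, y in enumerate(s.obs):
            start = (
                (s.start_week + dt.timedelta(weeks=t)).isoformat()
                if isinstance(s.start_week, dt.date) else ""
            )
            rows.append((s.patient_id, t, start, int(y)))
    pd.DataFrame(
        rows, columns=["patient_id", "week_index", "week_start", "crisis"]
    ).to_csv(path, index=False)


def read_weekly_csv(path: str | Path) -> list[CrisisSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for pid, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("week_index")
        start = None
        if "week_start" in g.columns and isinstance(
            g["week_start"].iloc[0], str
        ):
            start = dt.date.fromisoformat(g["week_start"].iloc[0])
        out.append(CrisisSeries(
            patient_id=str(pid), obs=g["crisis"].to_numpy(dtype=np.int8),
            start_week=start,
        ))
    return out


def write_params_csv(
    cohort: Sequence[CrisisSeries],
    params_map: Mapping[str, ModelParams],
    path: str | Path,
    fits: Mapping[str, FitResult] | None = None,
    min_history_weeks: int = 13,
) -> None:
    """Parameter table: patient_id, p, q, r, loglik, n_iter, converged, source."""
    rows = []
    for s in cohort:
        m = params_map[s.patient_id]
        individual = len(s) >= min_history_weeks and (
            fits is None or s.patient_id in fits
        )
        fit = fits.get(s.patient_id) if fits else None
        rows.append({
            "patient_id": s.patient_id, "p": m.p, "q": m.q, "r": m.r,
            "loglik": fit.loglik if fit and individual else np.nan,
            "n_iter": fit.n_iter if fit and individual else pd.NA,
            "converged": fit.converged if fit and individual else pd.NA,
            "source": "individual" if individual else "pooled",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_csv(path: str | Path) -> dict[str, ModelParams]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return {
        row["patient_id"]: ModelParams(
            p=float(row["p"]), q=float(row["q"]), r=float(row["r"])
        )
        for _, row in df.iterrows()
    }


def write_plans_csv(
    plans: Sequence[MonitoringPlan] | Mapping[str, MonitoringPlan],
    path: str | Path,
) -> None:
    items = plans.values() if isinstance(plans, Mapping) else plans
    pd.DataFrame(
        [{"patient_id": p.patient_id, "weeks_to_stable": p.weeks_to_stable}
         for p in items]
    ).to_csv(path, index=False)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file.

    Keys may be nested mappings (``policy: {tau: 0.35}``) or flat dotted
    keys (``policy.tau: 0.35``); flags on the command line override these
    values.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested: dict[str, dict] = {}
    scalars: dict[str, object] = {}
    for key, value in raw.items():
        if "." in key:
            section, sub = key.split(".", 1)
            nested.setdefault(section, {})[sub] = value
        elif isinstance(value, dict):
            nested.setdefault(key, {}).update(value)
        else:
            scalars[key] = value
    # tuples arrive from YAML as lists
    sim = nested.get("simulation", {})
    for k in ("range_p", "range_q", "range_r"):
        if k in sim:
            sim[k] = tuple(sim[k])
    return RunConfig(
        policy=_build(PolicyConfig, nested.get("policy", {})),
        fit=_build(FitConfig, nested.get("fit", {})),
        simulation=_build(SimConfig, sim),
        split_week=scalars.get("split_week"),
        paths=nested.get("paths", {}),
    )


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write deterministic test fixtures.

    ``toy``: the short sequences used by the brute-force enumeration
    oracle plus a 3-patient evaluation fixture.  ``small-cohort``: a
    100-patient, 120-week simulated mini-cohort (events + ground truth).
    """
    from .cohort_sim import SimConfig, cohort_to_series, simulate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "toy":
        toy = [
            CrisisSeries("toy-a", np.array([1, 0], dtype=np.int8)),
            CrisisSeries("toy-b", np.array([0, 1, 1, 0], dtype=np.int8)),
            CrisisSeries("toy-c", np.array([1, 0, 0, 1, 0, 1, 0, 0],
                                           dtype=np.int8)),
        ]
        path = out_dir / "toy_sequences.csv"
        write_weekly_csv(toy, path)
        written.append(path)
        rng = np.random.default_rng(seed)
        eval_fix = [
            CrisisSeries(f"eval-{i}", rng.integers(0, 2, 12).astype(np.int8))
            for i in range(3)
        ]
        path = out_dir / "eval_fixture.csv"
        write_weekly_csv(eval_fix, path)
        written.append(path)
    elif kind == "small-cohort":
        cfg = SimConfig(n_patients=100, n_weeks=120, train_weeks=96,
                        n_zero_r=10, seed=seed)
        patients = simulate_cohort(cfg)
        series = cohort_to_series(patients)
        path = out_dir / "mini_cohort_events.csv"
        write_events_csv(series_to_events(series), path)
        written.append(path)
        path = out_dir / "mini_cohort_truth.csv"
        rows = []
        for pt in patients:
            for t in range(cfg.n_weeks):
                rows.append({
                    "patient_id": pt.patient_id, "week": t,
                    "state": int(pt.states[t]), "crisis": int(pt.crises[t]),
                    "p": pt.params.p, "q": pt.params.q, "r": pt.params.r,
                })
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
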