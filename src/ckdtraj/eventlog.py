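"""Per-patient, time-ordered KDIGO stage event logs.

The event log is the shared substrate of process discovery and the
multistate model.  Each patient contributes a sequence of stage
observations at times measured in months since the index date; the
first event (time 0) is the baseline stage, subsequent events are
staged eGFR measurements strictly after the index date and no later
than the censoring date (the earliest of death, emigration and the
administrative end of study).

Conventions:

* one month = 30.4375 days (365.25 / 12), so month-scale summaries are
  calendar-independent;
* several measurements on one calendar day are averaged on the eGFR
  scale before staging, which keeps per-patient event times strictly
  increasing (a requirement of the panel likelihood);
* the baseline measurement may predate the index date by up to the
  183-day baseline window but its event time is pinned to 0: follow-up
  starts at the index date in the baseline stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ckdtraj.cohort import StudyWindow
from ckdtraj.staging import MERGED_STAGES, STAGES, assign_stage, merge_stage

__all__ = [
    "DAYS_PER_MONTH",
    "EventLog",
    "build_event_log",
    "merge_log",
    "trajectory_lengths",
    "write_event_log",
    "read_event_log",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 365.25 / 12  # 30.4375


@dataclass(frozen=True)
class EventLog:
    """Stage observations and censoring times for a set of patients.

    Attributes
    ----------
    events : DataFrame
        Columns ``patient_id``, ``time_months``, ``stage``; sorted by
        patient then time, strictly increasing within patient, first
        event of every patient at time 0.
    censoring : DataFrame
        Columns ``patient_id``, ``censor_months``; one row per patient.
    stage_space : str
        ``"full"`` (G1..G5) or ``"merged"`` (G1/2, G3, G4/5).
    """

    events: pd.DataFrame
    censoring: pd.DataFrame
    stage_space: str = "full"

    def __post_init__(self):
        ev, cz = self.events, self.censoring
        if self.stage_space not in ("full", "merged"):
            raise ValueError("stage_space must be 'full' or 'merged'")
        labels = STAGES if self.stage_space == "full" else MERGED_STAGES
        if not ev["stage"].isin(labels).all():
            bad = sorted(set(ev["stage"]) - set(labels))
            raise ValueError(f"stage labels {bad} not in {self.stage_space} space")
        if ev["time_months"].lt(0).any():
            raise ValueError("event times must be non-negative")
        if len(ev):
            pid = ev["patient_id"].to_numpy()
            t = ev["time_months"].to_numpy(dtype=float)
            same = pid[1:] == pid[:-1]
            if np.any(same & (np.diff(t) <= 0)):
                raise ValueError("event times must be strictly increasing per patient")
            starts = np.concatenate([[True], ~same])
            if np.any(t[starts] != 0.0):
                raise ValueError("every patient's first event must be at time 0")
        merged = ev.merge(cz, on="patient_id", validate="many_to_one")
        if (merged["time_months"] > merged["censor_months"] + 1e-9).any():
            raise ValueError("event after censoring time")

    @property
    def patients(self) -> np.ndarray:
        return self.censoring["patient_id"].to_numpy()

    @property
    def n_patients(self) -> int:
        return len(self.censoring)

    def sequences(self):
        """Yield ``(patient_id, times, stages)`` per patient, in id order."""
        for pid, grp in self.events.groupby("patient_id", sort=True):
            yield pid, grp["time_months"].to_numpy(), grp["stage"].to_numpy()


def build_event_log(cohort: pd.DataFrame, measurements: pd.DataFrame,
                    window: StudyWindow | None = None,
                    terminations: pd.DataFrame | None = None) -> EventLog:
    """Assemble the full-stage event log for an eligible cohort.

    Parameters
    ----------
    cohort : DataFrame
        Output of :func:`ckdtraj.cohort.build_cohort` (needs
        ``patient_id``, ``index_date``, ``baseline_stage``).
    measurements : DataFrame
        ``patient_id, date, egfr`` (already converted to eGFR).
    terminations : DataFrame, optional
        ``patient_id, date`` of death or emigration; censoring is the
        earlier of this date and the study end.

    Measurements after a patient's censoring date are dropped (count
    logged).  Measurements between the baseline Scr date and the index
    date are not replayed: the trajectory starts at the baseline stage
    at time 0.
    """
    window = window or StudyWindow()
    meas = measurements.copy()
    meas["date"] = pd.to_datetime(meas["date"])

    idx = cohort.set_index("patient_id")
    censor_date = pd.Series(window.study_end, index=idx.index)
    if terminations is not None and len(terminations):
        term = terminations.copy()
        term["date"] = pd.to_datetime(term["date"])
        t = term.groupby("patient_id")["date"].min()
        censor_date = pd.concat([censor_date, t], axis=1).min(axis=1)[censor_date.index]
    censor_months = ((censor_date - idx["index_date"]).dt.days / DAYS_PER_MONTH)

    m = meas.merge(idx[["index_date"]], left_on="patient_id", right_index=True)
    m = m.reset_index(drop=True)
    m = m[m["date"] > m["index_date"]]
    n_before_censor = len(m)
    m = m[m["date"] <= censor_date.reindex(m["patient_id"]).to_numpy()]
    dropped = n_before_censor - len(m)
    if dropped:
        logger.info("dropped %d measurement(s) after censoring", dropped)

    # average same-day eGFR values, then stage
    daily = (m.groupby(["patient_id", "date", "index_date"], as_index=False)["egfr"].mean())
    daily["time_months"] = (daily["date"] - daily["index_date"]).dt.days / DAYS_PER_MONTH
    daily["stage"] = assign_stage(daily["egfr"].to_numpy()) if len(daily) else pd.Series(dtype=str)

    base = pd.DataFrame({
        "patient_id": idx.index,
        "time_months": 0.0,
        "stage": idx["baseline_stage"].to_numpy(),
    })
    events = pd.concat([base, daily[["patient_id", "time_months", "stage"]]],
                       ignore_index=True)
    events = events.sort_values(["patient_id", "time_months"], ignore_index=True)
    censoring = pd.DataFrame({"patient_id": idx.index,
                              "censor_months": censor_months.to_numpy()}).reset_index(drop=True)
    return EventLog(events=events, censoring=censoring, stage_space="full")


def merge_log(log: EventLog) -> EventLog:
    """Map a full-stage log onto the merged three-state space.

    Events are retained one-to-one; consecutive observations that land
    in the same merged stage are kept (they become self-loops of the
    process map, the "remained at" transitions).
    """
    if log.stage_space != "full":
        raise ValueError("log is already in the merged stage space")
    events = log.events.copy()
    events["stage"] = merge_stage(events["stage"].to_numpy())
    return replace(log, events=events, stage_space="merged")


def trajectory_lengths(log: EventLog) -> tuple[pd.Series, dict[str, float]]:
    """Per-patient trajectory lengths (observed events) with median/IQR.

    Returns ``(counts, summary)`` where counts is indexed by patient_id
    and summary has keys ``median``, ``q1``, ``q3``.
    """
    counts = log.events.groupby("patient_id").size().rename("n_events")
    q1, med, q3 = np.percentile(counts.to_numpy(), [25, 50, 75])
    return counts, {"median": float(med), "q1": float(q1), "q3": float(q3)}


def write_event_log(log: EventLog, directory: str | Path) -> None:
    """Serialise a log as ``events.csv`` + ``censoring.csv``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    log.events.to_csv(d / "events.csv", index=False)
    log.censoring.assign(stage_space=log.stage_space).to_csv(d / "censoring.csv", index=False)


def read_event_log(directory: str | Path) -> EventLog:
    """Read a log written by :func:`write_event_log`."""
    d = Path(directory)
    events = pd.read_csv(d / "events.csv")
    censoring = pd.read_csv(d / "censoring.csv")
    space = censoring["stage_space"].iloc[0] if "stage_space" in censoring else "full"
    return EventLog(events=events, censoring=censoring[["patient_id", "censor_months"]],
                    stage_space=space)
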