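"""New-user / active-comparator cohort selection.

The design: patients enter the cohort at their first-ever dispensation
of either the exposure drug class (PPI) or the active comparator (H2B)
inside an enrolment window; a preceding washout year with no
dispensation of either class guarantees "new use".  The index date is
that first dispensation; group membership is the class dispensed.
Eligibility further requires a baseline serum-creatinine measurement
within six months before (or on) the index date, adult age, and a
baseline eGFR in [15, 60) mL/min/1.73 m² — i.e. CKD stages G3A-G4 at
entry, excluding kidney failure.

Exclusions are tallied in a fixed order (new-user -> baseline Scr ->
age -> eGFR >= 60 -> eGFR < 15) so the selection flowchart is
reproducible; under this sequential order the tally counts are disjoint
and sum to candidates minus included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ckdtraj.staging import assign_stage, compute_egfr, umol_to_mgdl

__all__ = [
    "StudyWindow",
    "BASELINE_WINDOW_DAYS",
    "EXCLUSION_ORDER",
    "identify_new_users",
    "baseline_egfr",
    "apply_eligibility",
    "build_cohort",
    "measurements_to_egfr",
]

logger = logging.getLogger(__name__)

#: "Less than 6 months before the index date" realised as a fixed day
#: count so the filter is calendar-independent.
BASELINE_WINDOW_DAYS = 183

#: Fixed order of the sequential eligibility filters.
EXCLUSION_ORDER = (
    "not_new_user",
    "no_baseline_scr",
    "age_under_18",
    "egfr_60_or_more",
    "egfr_below_15",
)


@dataclass(frozen=True)
class StudyWindow:
    """Calendar window of the study.

    ``washout_start``..``enrol_start`` is the look-back period used to
    ascertain no prior dispensation; first dispensations inside
    ``[enrol_start, enrol_end]`` define new users; follow-up is
    administratively censored at ``study_end``.
    """

    washout_start: pd.Timestamp = field(default=pd.Timestamp("2006-01-01"))
    enrol_start: pd.Timestamp = field(default=pd.Timestamp("2007-01-01"))
    enrol_end: pd.Timestamp = field(default=pd.Timestamp("2010-12-31"))
    study_end: pd.Timestamp = field(default=pd.Timestamp("2011-12-31"))

    def __post_init__(self):
        w, a, b, e = (pd.Timestamp(self.washout_start), pd.Timestamp(self.enrol_start),
                      pd.Timestamp(self.enrol_end), pd.Timestamp(self.study_end))
        object.__setattr__(self, "washout_start", w)
        object.__setattr__(self, "enrol_start", a)
        object.__setattr__(self, "enrol_end", b)
        object.__setattr__(self, "study_end", e)
        if not (w < a <= b < e):
            raise ValueError("require washout_start < enrol_start <= enrol_end < study_end")


def identify_new_users(dispensations: pd.DataFrame, window: StudyWindow | None = None) -> pd.DataFrame:
    """Resolve new users, their group and index date from dispensations.

    Parameters
    ----------
    dispensations : DataFrame
        Columns ``patient_id``, ``date``, ``drug_class`` (values ``PPI``
        or ``H2B``).  Order is irrelevant.
    window : StudyWindow, optional

    Returns
    -------
    DataFrame with columns ``patient_id``, ``group``, ``index_date``,
    one row per new user, sorted by patient_id.  A patient is a new user
    iff their earliest dispensation of either class falls inside the
    enrolment window; any dispensation before ``enrol_start`` (prior
    use) excludes them, as does a first dispensation after
    ``enrol_end``.  Patients whose earliest date carries both drug
    classes are excluded as group-ambiguous (logged).
    """
    window = window or StudyWindow()
    disp = dispensations.copy()
    disp["date"] = pd.to_datetime(disp["date"])
    bad_class = ~disp["drug_class"].isin(("PPI", "H2B"))
    if bad_class.any():
        raise ValueError(f"unknown drug_class values: {sorted(disp.loc[bad_class, 'drug_class'].unique())}")
    if (disp["date"] < window.washout_start).any() or (disp["date"] > window.study_end).any():
        raise ValueError("dispensation dates outside the study data window")

    first = disp.groupby("patient_id")["date"].min().rename("index_date")
    in_window = (first >= window.enrol_start) & (first <= window.enrol_end)

    on_first = disp.merge(first, on="patient_id")
    on_first = on_first[on_first["date"] == on_first["index_date"]]
    nclass = on_first.groupby("patient_id")["drug_class"].nunique()
    ambiguous = nclass[nclass > 1].index
    if len(ambiguous):
        logger.info("excluding %d patient(s) with same-day first dispensation of both classes",
                    len(ambiguous))

    keep = first.index[in_window].difference(ambiguous)
    group = (on_first[on_first["patient_id"].isin(keep)]
             .groupby("patient_id")["drug_class"].first().rename("group"))
    out = pd.concat([group, first.loc[keep]], axis=1).reset_index()
    return out.sort_values("patient_id", ignore_index=True)


def baseline_egfr(measurements: pd.DataFrame, index_dates: pd.DataFrame) -> pd.DataFrame:
    """Latest eGFR measurement on or before each patient's index date and
    within the 183-day baseline window.

    Parameters
    ----------
    measurements : DataFrame
        Columns ``patient_id``, ``date``, ``egfr``.
    index_dates : DataFrame
        Columns ``patient_id``, ``index_date`` (one row per patient).

    Returns
    -------
    DataFrame ``patient_id, baseline_egfr, baseline_date`` containing
    only patients with a qualifying measurement; absence drives the
    "no baseline Scr" exclusion downstream.
    """
    meas = measurements.copy()
    meas["date"] = pd.to_datetime(meas["date"])
    m = meas.merge(index_dates[["patient_id", "index_date"]], on="patient_id")
    lag = (m["index_date"] - m["date"]).dt.days
    ok = m[(lag >= 0) & (lag < BASELINE_WINDOW_DAYS)]
    if ok.empty:
        return pd.DataFrame(columns=["patient_id", "baseline_egfr", "baseline_date"])
    latest = ok.sort_values(["patient_id", "date"]).groupby("patient_id").tail(1)
    return (latest.rename(columns={"egfr": "baseline_egfr", "date": "baseline_date"})
            [["patient_id", "baseline_egfr", "baseline_date"]]
            .sort_values("patient_id", ignore_index=True))


def apply_eligibility(candidates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sequential eligibility filter with a fixed-order exclusion tally.

    ``candidates`` has one row per patient with columns ``is_new_user``
    (bool), ``baseline_egfr`` (NaN if no qualifying measurement) and
    ``age``.  Returns the included subset and an ordered tally mapping
    each criterion of :data:`EXCLUSION_ORDER` to the number of patients
    removed at that step.
    """
    tally: dict[str, int] = {}
    df = candidates
    m = df["is_new_user"].astype(bool)
    tally["not_new_user"] = int((~m).sum())
    df = df[m]

    m = df["baseline_egfr"].notna()
    tally["no_baseline_scr"] = int((~m).sum())
    df = df[m]

    m = df["age"] >= 18
    tally["age_under_18"] = int((~m).sum())
    df = df[m]

    m = df["baseline_egfr"] < 60
    tally["egfr_60_or_more"] = int((~m).sum())
    df = df[m]

    m = df["baseline_egfr"] >= 15
    tally["egfr_below_15"] = int((~m).sum())
    df = df[m]

    assert sum(tally.values()) == len(candidates) - len(df)
    return df.reset_index(drop=True), tally


def measurements_to_egfr(measurements: pd.DataFrame, demographics: pd.DataFrame,
                         value: str = "egfr") -> pd.DataFrame:
    """Normalise a measurement table to ``patient_id, date, egfr``.

    ``value`` selects the column carrying the observation: ``egfr``
    (pass-through), ``scr_mgdl`` or ``scr_umol`` (converted through the
    CKD-EPI equation using age and sex from ``demographics``, which
    needs columns ``patient_id, age, sex``).
    """
    meas = measurements.copy()
    meas["date"] = pd.to_datetime(meas["date"])
    if value == "egfr":
        return meas[["patient_id", "date", "egfr"]]
    if value not in ("scr_mgdl", "scr_umol"):
        raise ValueError("value must be one of 'egfr', 'scr_mgdl', 'scr_umol'")
    merged = meas.merge(demographics[["patient_id", "age", "sex"]], on="patient_id",
                        how="left", validate="many_to_one")
    if merged["age"].isna().any():
        missing = merged.loc[merged["age"].isna(), "patient_id"].unique()
        raise ValueError(f"no demographics for patient(s) {missing[:5].tolist()} — cannot convert creatinine")
    scr = merged[value].to_numpy(dtype=float)
    if value == "scr_umol":
        scr = umol_to_mgdl(scr)
    merged["egfr"] = compute_egfr(scr, merged["age"].to_numpy(), merged["sex"].to_numpy())
    return merged[["patient_id", "date", "egfr"]]


def build_cohort(dispensations: pd.DataFrame, measurements: pd.DataFrame,
                 covariates: pd.DataFrame, window: StudyWindow | None = None,
                 value: str = "egfr") -> tuple[pd.DataFrame, dict[str, int]]:
    """Full cohort construction: new users + baseline eGFR + eligibility.

    Parameters
    ----------
    dispensations, measurements, covariates : DataFrame
        The three input tables; ``covariates`` must carry ``patient_id``,
        ``age``, ``sex`` and may carry arbitrary additional flag columns
        that are passed through to the cohort records.
    value : str
        Which measurement column holds the observation (see
        :func:`measurements_to_egfr`).

    Returns
    -------
    (cohort, tally) where cohort rows carry patient_id, group,
    index_date, baseline_egfr, baseline_date, baseline_stage, age, sex
    and any extra covariate columns, and tally is the ordered exclusion
    count per criterion.
    """
    window = window or StudyWindow()
    meas = measurements_to_egfr(measurements, covariates, value=value)
    new_users = identify_new_users(dispensations, window)
    baseline = baseline_egfr(meas, new_users)

    all_ids = pd.Index(sorted(dispensations["patient_id"].unique()), name="patient_id")
    cand = pd.DataFrame(index=all_ids).reset_index()
    cand = (cand.merge(new_users.assign(is_new_user=True), on="patient_id", how="left")
            .merge(baseline, on="patient_id", how="left"))
    # the dispensation-derived group/index_date are authoritative; drop
    # any identically named covariate columns
    overlap = (set(covariates.columns) - {"patient_id"}) & set(cand.columns)
    cand = cand.merge(covariates.drop(columns=sorted(overlap)), on="patient_id",
                      how="left", validate="one_to_one")
    cand["is_new_user"] = cand["is_new_user"].eq(True)
    # age may be missing for non-candidates; treat missing as ineligible
    cand["age"] = cand["age"].fillna(-1)

    included, tally = apply_eligibility(cand)
    if len(included):
        included = included.assign(baseline_stage=assign_stage(included["baseline_egfr"].to_numpy()))
    else:
        included = included.assign(baseline_stage=pd.Series(dtype=str))
    included = included.drop(columns=["is_new_user"])
    logger.info("cohort built: %d included, exclusions %s", len(included), tally)
    return included, tally
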