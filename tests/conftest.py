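import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ckdtraj.eventlog import EventLog

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_two_patient_log():
    """Two patients in the full stage space: [G3A, G3B] and [G3A, G3A]."""
    events = pd.DataFrame({
        "patient_id": ["a", "a", "b", "b"],
        "time_months": [0.0, 1.0, 0.0, 2.0],
        "stage": ["G3A", "G3B", "G3A", "G3A"],
    })
    censoring = pd.DataFrame({"patient_id": ["a", "b"], "censor_months": [6.0, 6.0]})
    return EventLog(events=events, censoring=censoring, stage_space="full")


@pytest.fixture
def five_candidate_tables():
    """Five hand-written candidates, each failing exactly one criterion.

    1. prior dispensation in the washout year (not a new user)
    2. no creatinine measurement within six months of the index date
    3. under 18 at index
    4. baseline eGFR 72 (not CKD)
    5. baseline eGFR 12 (kidney failure)
    """
    disp = pd.DataFrame([
        ("p1", "2006-06-01", "PPI"), ("p1", "2008-01-01", "PPI"),
        ("p2", "2007-03-01", "PPI"),
        ("p3", "2007-04-01", "H2B"),
        ("p4", "2008-05-01", "PPI"),
        ("p5", "2009-06-01", "H2B"),
    ], columns=["patient_id", "date", "drug_class"])
    meas = pd.DataFrame([
        ("p1", "2007-12-15", 50.0),
        ("p2", "2006-08-01", 50.0),    # 7 months before index: does not qualify
        ("p3", "2007-03-20", 45.0),
        ("p4", "2008-05-01", 72.0),
        ("p5", "2009-05-30", 12.0),
    ], columns=["patient_id", "date", "egfr"])
    cov = pd.DataFrame({
        "patient_id": ["p1", "p2", "p3", "p4", "p5"],
        "age": [70, 66, 17, 55, 80],
        "sex": ["female", "male", "female", "male", "female"],
    })
    return disp, meas, cov
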