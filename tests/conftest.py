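"""Shared fixtures: hand-built micro-datasets and study-like simulations."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from phenoval import builtin_definitions, default_config, simulate
from phenoval.data_model import StudyDataset, validate_dataset
from phenoval.simulate import calibrated_scores

D_TRAIN = dt.date(2010, 6, 1)
D_TEST = dt.date(2016, 6, 1)


def make_dataset(
    patients=None, events=None, labs=None, flags=None, period="training"
) -> StudyDataset:
    """Build a small validated StudyDataset from row tuples.

    events: (pid, system, code[, date]); labs: (pid, test, value[, date]);
    flags: (pid, referral[, verdict]).  Patients default to the union of
    ids seen in the other tables (male, born 1980).
    """
    date = D_TRAIN if period == "training" else D_TEST
    events = [
        (e + (date,))[:4] if len(e) == 3 else e for e in (events or [])
    ]
    labs = [(l + (date,))[:4] if len(l) == 3 else l for l in (labs or [])]
    flags = [
        (f + ("not_reviewed",))[:3] if len(f) == 2 else f for f in (flags or [])
    ]
    if patients is None:
        ids = sorted(
            {e[0] for e in events} | {l[0] for l in labs} | {f[0] for f in flags}
        )
        patients = [(pid, "male", 1980) for pid in ids]
    ds = StudyDataset(
        patients=pd.DataFrame(patients, columns=["patient_id", "sex", "birth_year"]),
        events=pd.DataFrame(
            [(e[0], e[3], e[1], e[2]) for e in events],
            columns=["patient_id", "date", "system", "code"],
        ),
        labs=pd.DataFrame(
            [(l[0], l[3], l[1], l[2]) for l in labs],
            columns=["patient_id", "date", "test", "value"],
        ),
        flags=pd.DataFrame(
            flags, columns=["patient_id", "diabetologist_referral", "chart_review_verdict"]
        ),
        period=period,
    )
    return validate_dataset(ds)


@pytest.fixture(scope="session")
def studylike_small():
    """Study-like simulation at moderate size, shared across tests."""
    cfg = default_config(n_train=20_000, n_test=20_000, seed=20210211 % 2**16)
    train, test, truth = simulate(cfg)
    return cfg, train, test, truth


@pytest.fixture(scope="session")
def big_test_sim():
    """Large test-period simulation (n=50 000) with exact posterior scores."""
    cfg = default_config(n_train=100, n_test=50_000, seed=424242)
    _, test, truth = simulate(cfg)
    scores = calibrated_scores(test, cfg)
    defs = builtin_definitions(cfg.basal_insulin_codes)
    return cfg, test, truth, scores, defs
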