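"""Gold-standard cohort: screening criteria, adjudication, exclusions, controls."""

import numpy as np
import pandas as pd
import pytest

from phenoval.cohort import (
    CohortConfig,
    CohortError,
    adjudicate,
    build_cases,
    build_cohort,
    sample_controls,
    screen_possible_cases,
)

from conftest import make_dataset


def _truth(pairs):
    return pd.DataFrame(
        [(p, t, False) for p, t in pairs],
        columns=["patient_id", "latent_t1d", "latent_hemophilia"],
    )


def test_cpr_only_below_02_matches_c5_not_c2():
    ds = make_dataset(labs=[("p", "serum_cpr", 0.15)])
    assert screen_possible_cases(ds) == {"p": {"c5"}}


def test_cpr_thresholds_are_strict():
    """CPR exactly at a threshold does not qualify ("less than")."""
    ds = make_dataset(
        events=[
            ("p", "medication", "insulin_aspart"),
            ("p", "icd10_confirmed", "E872"),
        ],
        labs=[("p", "serum_cpr", 0.6)],
    )
    assert screen_possible_cases(ds) == {}
    ds2 = make_dataset(
        events=[
            ("p", "medication", "insulin_aspart"),
            ("p", "icd10_confirmed", "E872"),
        ],
        labs=[("p", "serum_cpr", 0.59)],
    )
    assert screen_possible_cases(ds2) == {"p": {"c2"}}


def test_c2_requires_all_three_components():
    # insulin + low CPR but no ketoacidosis diagnosis
    ds = make_dataset(
        events=[("p", "medication", "insulin_glargine")],
        labs=[("p", "serum_cpr", 0.4)],
    )
    assert screen_possible_cases(ds) == {}


def test_remaining_criteria():
    ds = make_dataset(
        events=[("c1p", "icd10_confirmed", "E101")],
        labs=[("c3p", "gad_antibody", 1.0), ("neg", "ia2_antibody", 0.0)],
        flags=[("c4p", True), ("neg", False)],
    )
    out = screen_possible_cases(ds)
    assert out == {"c1p": {"c1"}, "c3p": {"c3"}, "c4p": {"c4"}}


def test_patient_with_no_records_matches_nothing():
    ds = make_dataset(patients=[("lonely", "male", 1980)])
    assert screen_possible_cases(ds) == {}


def test_screening_is_monotone_under_added_records():
    """Adding events/labs never removes a matched criterion."""
    base = make_dataset(
        events=[("p", "medication", "insulin_aspart")],
        labs=[("p", "serum_cpr", 0.5)],
        flags=[("p", True)],
    )
    before = screen_possible_cases(base).get("p", set())
    richer = make_dataset(
        events=[
            ("p", "medication", "insulin_aspart"),
            ("p", "icd10_confirmed", "E872"),
            ("p", "icd10_confirmed", "E10"),
        ],
        labs=[("p", "serum_cpr", 0.5), ("p", "serum_cpr", 0.1), ("p", "gad_antibody", 1.0)],
        flags=[("p", True)],
    )
    after = screen_possible_cases(richer).get("p", set())
    assert before <= after
    assert after == {"c1", "c2", "c3", "c4", "c5"}


def test_adjudication_error_rates():
    possible = {f"p{i}": {"c1"} for i in range(1000)}
    truth = _truth([(f"p{i}", i % 2 == 0) for i in range(1000)])
    exact = adjudicate(possible, truth=truth, error_rate=0.0, seed=1)
    assert all(
        (v == "true_t1d") == (int(p[1:]) % 2 == 0) for p, v in exact.items()
    )
    flipped = adjudicate(possible, truth=truth, error_rate=1.0, seed=1)
    assert all(
        (v == "true_t1d") != (int(p[1:]) % 2 == 0) for p, v in flipped.items()
    )
    noisy = adjudicate(possible, truth=truth, error_rate=0.1, seed=1)
    n_flip = sum(noisy[p] != exact[p] for p in possible)
    assert abs(n_flip - 100) <= 3 * np.sqrt(1000 * 0.1 * 0.9)
    assert noisy == adjudicate(possible, truth=truth, error_rate=0.1, seed=1)


def test_adjudication_requires_truth_for_every_screened_patient():
    with pytest.raises(CohortError):
        adjudicate({"ghost": {"c1"}}, truth=_truth([("p", True)]))


def test_case_exclusions():
    ds = make_dataset(
        events=[
            ("t2d", "icd10_suspected", "E11"),
            ("tx", "procedure", "150999910"),
            ("ok", "icd10_confirmed", "E14"),
        ],
    )
    verdicts = {"t2d": "true_t1d", "tx": "true_t1d", "ok": "true_t1d", "no": "not_t1d"}
    cases, excluded = build_cases(verdicts, ds)
    assert cases == {"ok"}
    assert excluded == {"t2d": "t2d_code", "tx": "pancreas_transplant"}


def test_control_sampling_sizes_and_determinism():
    patients = [(f"p{i:03d}", "male", 1980) for i in range(502)]
    ds = make_dataset(patients=patients)
    reviewed = {"p000", "p001"}
    controls = sample_controls(ds, reviewed, n_cases=2, ratio=100, seed=5)
    assert len(controls) == 200
    assert controls == sample_controls(ds, reviewed, n_cases=2, ratio=100, seed=5)
    assert not controls & reviewed
    limited = sample_controls(ds, set(ds.patient_ids()) - set(list(ds.patient_ids())[:150]),
                              n_cases=2, ratio=100, seed=5)
    assert len(limited) == 150  # pool-limited


def test_controls_never_carry_a_t1d_code():
    ds = make_dataset(
        patients=[(f"p{i}", "male", 1980) for i in range(20)],
        events=[("p1", "icd10_suspected", "E10"), ("p2", "icd10_confirmed", "E109")],
    )
    controls = sample_controls(ds, set(), n_cases=1, ratio=100, seed=0)
    assert "p1" not in controls and "p2" not in controls


def test_empty_pool_raises():
    ds = make_dataset(patients=[("a", "male", 1980)])
    with pytest.raises(CohortError, match="pool"):
        sample_controls(ds, {"a"}, n_cases=1, ratio=10, seed=0)


def test_cohort_on_simulator_recovers_latent_cases(studylike_small):
    """With perfect adjudication, cases = screened latent T1D minus exclusions."""
    cfg, train, _, truth = studylike_small
    cc = CohortConfig(insulin_codes=cfg.insulin_codes)
    cohort = build_cohort(train, truth=truth, config=cc, seed=2)
    by_status = {
        s: set(g["patient_id"]) for s, g in cohort.groupby("status")
    }
    cases = by_status.get("case", set())
    controls = by_status.get("control", set())
    assert not cases & controls
    latent = set(truth.loc[truth["latent_t1d"], "patient_id"]) & train.patient_ids()
    screened = set(screen_possible_cases(train, cc))
    _, excluded = build_cases(
        adjudicate(screen_possible_cases(train, cc), truth=truth, seed=2),
        train,
        cc,
    )
    assert cases == (latent & screened) - set(excluded)
    # controls: never reviewed, never T1D-coded
    assert not controls & screened
    assert len(controls) <= round(cc.control_ratio * len(cases))
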