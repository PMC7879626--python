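"""Synthetic claims generator: determinism, calibration of emissions, oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from phenoval.data_model import validate_dataset, write_dataset
from phenoval.definitions import builtin_definitions, pred
from phenoval.simulate import (
    CodeEmission,
    ConfigError,
    analytic_definition_performance,
    calibrated_scores,
    default_config,
    simulate,
    true_definition_performance,
)

from conftest import make_dataset


def test_zero_prevalence_means_no_latent_cases():
    cfg = default_config(n_train=1000, n_test=0, t1d_prevalence=0.0, seed=3)
    _, _, truth = simulate(cfg)
    assert truth["latent_t1d"].sum() == 0


def test_full_coding_sensitivity_tags_every_case():
    table = tuple(
        dataclasses.replace(e, t1d=1.0) if e.code == "E10" and e.system == "icd10_confirmed" else e
        for e in default_config().emission_table
    )
    cfg = default_config(n_train=3000, n_test=0, emission_table=table, seed=4)
    train, _, truth = simulate(cfg)
    cases = set(truth.loc[truth["latent_t1d"], "patient_id"])
    ev = train.events
    coded = set(
        ev.loc[(ev["system"] == "icd10_confirmed") & (ev["code"] == "E10"), "patient_id"]
    )
    assert cases <= coded


def test_latent_count_within_three_binomial_sds():
    cfg = default_config(n_train=0, n_test=20_000, t1d_prevalence=0.005, seed=9)
    _, _, truth = simulate(cfg)
    sd = np.sqrt(20_000 * 0.005 * 0.995)
    assert abs(truth["latent_t1d"].sum() - 100) <= 3 * sd


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = default_config(n_train=500, n_test=500, seed=11)
    for d in ("a", "b"):
        train, test, _ = simulate(cfg)
        write_dataset(train, tmp_path / d / "train")
        write_dataset(test, tmp_path / d / "test")
    for sub in ("train", "test"):
        for name in ("patients", "events", "labs", "flags"):
            f = f"{sub}/{name}.csv"
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()


def test_outputs_pass_validation(studylike_small):
    _, train, test, truth = studylike_small
    validate_dataset(train)
    validate_dataset(test)
    assert not (train.patient_ids() & test.patient_ids())
    assert set(truth["patient_id"]) == train.patient_ids() | test.patient_ids()


def test_emission_frequencies_converge_to_table():
    """Empirical per-code frequencies match the emission table within 3 SDs."""
    cfg = default_config(n_train=0, n_test=50_000, seed=13)
    _, test, truth = simulate(cfg)
    latent_t1d = truth.set_index("patient_id")["latent_t1d"]
    classes = {
        "background": set(truth.loc[~truth.latent_t1d & ~truth.latent_hemophilia, "patient_id"]),
        "t1d": set(truth.loc[truth.latent_t1d, "patient_id"]),
    }
    ev = test.events
    for e in cfg.emission_table:
        if e.code not in ("E10", "114010970", "insulin_glargine"):
            continue
        carriers = set(
            ev.loc[(ev["system"] == e.system) & (ev["code"] == e.code), "patient_id"]
        )
        for cls, ids in classes.items():
            p = getattr(e, cls)
            n = len(ids)
            sd = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(len(carriers & ids) / n - p) <= max(3 * sd, 1e-4), (e.code, cls)


def test_missing_definition_code_is_config_error():
    cfg = default_config(
        emission_table=tuple(
            e for e in default_config().emission_table if e.code != "114010970"
        )
    )
    defs = builtin_definitions(cfg.basal_insulin_codes)
    with pytest.raises(ConfigError, match="114010970"):
        cfg.require_codes(defs)


def test_true_performance_empty_and_leaked_definitions():
    ds = make_dataset(
        patients=[("a", "male", 1980), ("b", "male", 1980)],
        events=[("a", "procedure", "170009990")],
    )
    truth = pd.DataFrame(
        {"patient_id": ["a", "b"], "latent_t1d": [True, False],
         "latent_hemophilia": [False, False]}
    )
    nobody = pred("procedure", "999999999")
    from phenoval.definitions import CaseDefinition

    perf = true_definition_performance(CaseDefinition("none", nobody), ds, truth)
    assert perf.tp == perf.fp == 0
    assert perf.ppv is None  # undefined, flagged rather than NaN
    leaked = true_definition_performance(
        CaseDefinition("leak", pred("procedure", "170009990")), ds, truth
    )
    assert leaked.sensitivity == 1.0 and leaked.ppv == 1.0


def test_independent_definition_has_ppv_equal_prevalence():
    """A code independent of the latent class gives PPV ≈ prevalence."""
    cfg = default_config(
        n_train=0,
        n_test=20_000,
        t1d_prevalence=0.005,
        seed=21,
        emission_table=default_config().emission_table
        + (CodeEmission("procedure", "179999990", 0.10, 0.10, 0.10),),
    )
    _, test, truth = simulate(cfg)
    from phenoval.definitions import CaseDefinition

    d = CaseDefinition("indep", pred("procedure", "179999990"))
    perf = true_definition_performance(d, test, truth)
    se = np.sqrt(0.005 * 0.995 / (0.10 * 20_000))
    assert perf.ppv == pytest.approx(0.005, abs=3 * se)
    ana = analytic_definition_performance(cfg, d)
    assert ana["ppv"] == pytest.approx(0.005, abs=1e-12)


def test_calibrated_scores_are_probabilities_matching_prevalence(big_test_sim):
    cfg, test, truth, scores, _ = big_test_sim
    p = scores["p_case"].to_numpy()
    assert ((p >= 0) & (p <= 1)).all()
    n_cases = truth.set_index("patient_id").loc[scores["patient_id"], "latent_t1d"].sum()
    # sum of posteriors estimates the number of latent cases
    assert p.sum() == pytest.approx(n_cases, rel=0.15)


def test_analytic_matches_empirical_performance(big_test_sim):
    cfg, test, truth, _, defs = big_test_sim
    for d in (defs[1], defs[2]):
        emp = true_definition_performance(d, test, truth)
        ana = analytic_definition_performance(cfg, d)
        n_cases = emp.tp + emp.fn
        se_sens = np.sqrt(ana["sensitivity"] * (1 - ana["sensitivity"]) / n_cases)
        assert emp.sensitivity == pytest.approx(ana["sensitivity"], abs=4 * se_sens)
        n_pos = emp.tp + emp.fp
        se_ppv = np.sqrt(ana["ppv"] * (1 - ana["ppv"]) / n_pos)
        assert emp.ppv == pytest.approx(ana["ppv"], abs=4 * se_ppv)


def test_invalid_probability_rejected():
    with pytest.raises(ConfigError):
        default_config(t1d_prevalence=1.5)
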