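"""Probabilistic confusion matrix, indexes, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenoval.metrics import (
    MetricsError,
    ProbabilisticConfusion,
    bootstrap_cis,
    evaluate_all,
    evaluate_definition,
    f_score,
    format_report,
    performance_indexes,
    probabilistic_confusion,
)


def scores_of(d):
    return pd.DataFrame({"patient_id": list(d), "p_case": list(d.values())})


FOUR_PATIENTS = scores_of({"A": 0.7, "B": 0.4, "C": 0.9, "D": 0.3})


def test_worked_example_confusion():
    conf = probabilistic_confusion(FOUR_PATIENTS, {"A", "C"})
    assert conf.tps == pytest.approx(1.6)
    assert conf.fps == pytest.approx(0.4)
    assert conf.fns == pytest.approx(0.7)
    assert conf.tns == pytest.approx(1.3)


def test_worked_example_indexes():
    est = performance_indexes(probabilistic_confusion(FOUR_PATIENTS, {"A", "C"}))
    assert est.sensitivity == pytest.approx(1.6 / 2.3)
    assert est.specificity == pytest.approx(1.3 / 1.7)
    assert est.ppv == pytest.approx(0.8)
    assert est.npv == pytest.approx(0.65)
    assert est.f_score == pytest.approx(
        2 * (1.6 / 2.3) * 0.8 / (1.6 / 2.3 + 0.8)
    )


def test_all_zero_probabilities():
    s = scores_of({"a": 0.0, "b": 0.0, "c": 0.0})
    conf = probabilistic_confusion(s, {"a"})
    assert (conf.tps, conf.fps, conf.fns, conf.tns) == (0.0, 1.0, 0.0, 2.0)
    est = performance_indexes(conf)
    assert est.sensitivity is None  # 0/0 flagged as undefined, not NaN
    assert est.ppv == 0.0


def test_equal_tps_fps_gives_ppv_half():
    est = performance_indexes(ProbabilisticConfusion(tps=2.0, fps=2.0, fns=1.0, tns=3.0))
    assert est.ppv == 0.5


def test_all_zero_confusion_is_an_error():
    with pytest.raises(MetricsError):
        performance_indexes(ProbabilisticConfusion(0, 0, 0, 0))


def test_positive_without_score_is_referential_error():
    with pytest.raises(MetricsError, match="without scores"):
        probabilistic_confusion(FOUR_PATIENTS, {"A", "Z"})


def test_f_score_from_printed_sensitivity_ppv():
    assert f_score(0.329, 0.333) == pytest.approx(0.331, abs=5e-4)
    assert f_score(None, 0.5) is None
    assert f_score(0.0, 0.0) is None


def brute_force_classical(truth_by_pid, positives):
    """Independent 2×2 oracle for 0/1 'probabilities'."""
    tp = sum(1 for p, t in truth_by_pid.items() if t and p in positives)
    fp = sum(1 for p, t in truth_by_pid.items() if not t and p in positives)
    fn = sum(1 for p, t in truth_by_pid.items() if t and p not in positives)
    tn = sum(1 for p, t in truth_by_pid.items() if not t and p not in positives)
    div = lambda a, b: a / b if b else None
    sens, ppv = div(tp, tp + fn), div(tp, tp + fp)
    f = (
        2 * sens * ppv / (sens + ppv)
        if sens is not None and ppv is not None and sens + ppv
        else None
    )
    return {
        "sensitivity": sens,
        "specificity": div(tn, fp + tn),
        "ppv": ppv,
        "npv": div(tn, fn + tn),
        "f_score": f,
    }


@given(st.data())
@settings(max_examples=50, deadline=None)
def test_degenerate_probabilities_equal_classical_confusion(data):
    n = data.draw(st.integers(2, 40))
    truth = {f"p{i}": data.draw(st.booleans()) for i in range(n)}
    pos = {p for p in truth if data.draw(st.booleans())}
    s = scores_of({p: 1.0 if t else 0.0 for p, t in truth.items()})
    est = performance_indexes(probabilistic_confusion(s, pos))
    expected = brute_force_classical(truth, pos)
    for k, v in expected.items():
        got = getattr(est, k)
        if v is None:
            assert got is None
        else:
            assert got == pytest.approx(v)


@given(
    st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=1, max_size=60)
)
@settings(max_examples=100, deadline=None)
def test_conservation_of_total_mass(rows):
    s = scores_of({f"p{i}": p for i, (p, _) in enumerate(rows)})
    pos = {f"p{i}" for i, (_, flag) in enumerate(rows) if flag}
    conf = probabilistic_confusion(s, pos)
    assert conf.n_total == pytest.approx(len(rows))


@given(
    st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=2, max_size=40)
)
@settings(max_examples=50, deadline=None)
def test_adding_certain_positive_never_decreases_sens_or_ppv(rows):
    s = scores_of({f"p{i}": p for i, (p, _) in enumerate(rows)})
    pos = {f"p{i}" for i, (_, flag) in enumerate(rows) if flag}
    before = performance_indexes(probabilistic_confusion(s, pos))
    s2 = pd.concat(
        [s, pd.DataFrame({"patient_id": ["extra"], "p_case": [1.0]})],
        ignore_index=True,
    )
    after = performance_indexes(probabilistic_confusion(s2, pos | {"extra"}))
    if before.sensitivity is not None:
        assert after.sensitivity >= before.sensitivity - 1e-12
    if before.ppv is not None:
        assert after.ppv >= before.ppv - 1e-12


def test_bootstrap_zero_width_for_identical_patients():
    s = scores_of({f"p{i}": 0.6 for i in range(30)})
    pos = set(s["patient_id"])
    ci = bootstrap_cis(s, pos, n_reps=100, seed=1)
    assert ci["ppv"] == (pytest.approx(0.6), pytest.approx(0.6))


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(0)
    s = scores_of({f"p{i}": float(p) for i, p in enumerate(rng.random(200))})
    pos = {f"p{i}" for i in range(0, 200, 3)}
    a = bootstrap_cis(s, pos, n_reps=300, seed=42)
    b = bootstrap_cis(s, pos, n_reps=300, seed=42)
    assert a == b
    c = bootstrap_cis(s, pos, n_reps=300, seed=43)
    assert a != c


def test_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(1)
    s = scores_of({f"p{i}": float(p) for i, p in enumerate(rng.random(500))})
    pos = {f"p{i}" for i in range(0, 500, 4)}
    est = evaluate_definition(s, pos, n_reps=400, seed=7)
    for k, ci in est.ci.items():
        assert ci is not None
        v = getattr(est, k)
        assert ci[0] - 1e-9 <= v <= ci[1] + 1e-9


def test_bootstrap_argument_validation():
    with pytest.raises(MetricsError):
        bootstrap_cis(FOUR_PATIENTS, {"A"}, n_reps=0)
    with pytest.raises(MetricsError):
        bootstrap_cis(FOUR_PATIENTS, {"A"}, n_reps=10, level=1.2)


def test_evaluate_all_complementary_definitions(studylike_small):
    cfg, _, test, truth = studylike_small
    from phenoval.definitions import CaseDefinition, pred
    from phenoval.simulate import calibrated_scores

    scores = calibrated_scores(test, cfg)
    d_pos = CaseDefinition("hba1c", pred("procedure", "160010010"))
    table = evaluate_all(scores, [d_pos], test, n_reps=50, seed=3)
    row = table.iloc[0]
    n_match = row["n"]
    # complementary definition: everyone NOT matching has complementary N
    assert 0 < n_match < test.n_patients
    assert row["prevalence_pct"] == pytest.approx(100 * n_match / test.n_patients)
    # both reporting scales: percentage column vs proportion-scale f-score
    assert row["sensitivity_pct"] > 1.0  # clearly on the % scale
    assert 0 <= row["f_score"] <= 1


def test_evaluate_all_handles_empty_definition(studylike_small):
    cfg, _, test, _ = studylike_small
    from phenoval.definitions import CaseDefinition, pred
    from phenoval.simulate import calibrated_scores

    scores = calibrated_scores(test, cfg)
    d_none = CaseDefinition("nobody", pred("procedure", "999999999"))
    table = evaluate_all(scores, [d_none], test, n_reps=0, seed=0)
    row = table.iloc[0]
    assert row["n"] == 0
    assert row["ppv_pct"] is None  # undefined PPV flagged as missing
    formatted = format_report(table)
    assert formatted.iloc[0]["ppv"] == "undefined"
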