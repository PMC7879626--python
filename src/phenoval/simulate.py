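"""Synthetic hospital claims/EHR generator with known latent T1D status.

The generator emulates the statistical structure a claims-code validation
study assumes, so every downstream stage (cohort building, feature
screening, model training, probabilistic evaluation) can be exercised and
checked against ground truth:

* a visiting-hospital population with a small true type-1-diabetes (T1D)
  prevalence and a small hemophilia prevalence (three mutually exclusive
  latent classes: background / T1D / hemophilia);
* imperfect coding — only about a third of true T1D patients carry the
  confirmed E10 diagnosis code;
* an injector-needle procedure code shared between T1D and hemophilia
  patients (the classic PPV confounder for needle-based definitions);
* basal-insulin medication codes, CSII syringe-pump procedure codes,
  serum C-peptide (CPR) lab values with class-specific lognormal
  distributions, GAD/IA2 autoantibody results, diabetologist referral
  flags, and a pancreas-transplant procedure;
* a large catalogue of class-independent noise codes so relative-risk
  feature screening has something to screen;
* disjoint training-period and test-period patient groups.

Within a latent class, every code is an independent Bernoulli draw per
patient per period, which makes the exact posterior P(T1D | codes) — and
hence a perfectly calibrated scorer — available in closed form
(:func:`calibrated_scores`), along with exact analytic sensitivity/PPV for
any boolean case definition (:func:`analytic_definition_performance`).
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DateWindow,
    StudyDataset,
    TEST_WINDOW,
    TRAINING_WINDOW,
    validate_dataset,
)
from .definitions import And, CaseDefinition, CodePredicate, positive_ids

CLASSES = ("background", "t1d", "hemophilia")

CPR_TEST_CODE = "160123450"
INSULIN_RECEPTOR_AB_TEST_CODE = "160234560"
PANCREAS_TRANSPLANT_CODE = "150999910"
KETOACIDOSIS_CODE = "E872"

#: stand-in for the configurable basal-insulin medication list
#: (long-acting, intermediate-acting and biphasic preparations)
DEFAULT_BASAL_INSULIN_CODES = (
    "insulin_glargine",
    "insulin_detemir",
    "insulin_degludec",
    "insulin_nph",
    "insulin_biphasic_aspart",
)
#: every insulin medication (basal + prandial), excluded from model features
DEFAULT_INSULIN_CODES = DEFAULT_BASAL_INSULIN_CODES + ("insulin_aspart",)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CodeEmission:
    """Per-period Bernoulli emission probabilities of one code, by class."""

    system: str
    code: str
    background: float
    t1d: float
    hemophilia: float

    def probs(self) -> np.ndarray:
        return np.array([self.background, self.t1d, self.hemophilia])


@dataclass(frozen=True)
class ClassRates:
    background: float
    t1d: float
    hemophilia: float

    def as_array(self) -> np.ndarray:
        return np.array([self.background, self.t1d, self.hemophilia])


@dataclass
class SimulationConfig:
    n_train: int = 20_000
    n_test: int = 20_000
    t1d_prevalence: float = 0.004
    hemophilia_prevalence: float = 0.002
    emission_table: tuple[CodeEmission, ...] = ()
    #: CPR measurement: emits the CPR-test procedure code and one lab row
    cpr_measured: ClassRates = field(
        default_factory=lambda: ClassRates(0.01, 0.60, 0.01)
    )
    #: lognormal (mu, sigma) of the measured CPR value (ng/ml) per class
    cpr_lognormal: dict = field(
        default_factory=lambda: {
            "background": (math.log(1.8), 0.5),
            "t1d": (math.log(0.15), 0.8),
            "hemophilia": (math.log(1.8), 0.5),
        }
    )
    antibody_measured: ClassRates = field(
        default_factory=lambda: ClassRates(0.005, 0.50, 0.005)
    )
    gad_positive: ClassRates = field(default_factory=lambda: ClassRates(0.02, 0.70, 0.02))
    ia2_positive: ClassRates = field(default_factory=lambda: ClassRates(0.02, 0.55, 0.02))
    referral: ClassRates = field(default_factory=lambda: ClassRates(0.0005, 0.30, 0.0005))
    #: age ~ round(Normal(mean, sd)) clipped to [0, 100], per class
    age_mean_sd: dict = field(
        default_factory=lambda: {
            "background": (46.0, 24.0),
            "t1d": (32.0, 18.0),
            "hemophilia": (38.0, 20.0),
        }
    )
    male_fraction: float = 0.445
    #: class-independent noise codes per namespace; probabilities ~ Beta(a, b)
    noise_codes: dict = field(
        default_factory=lambda: {
            "icd10_confirmed": 350,
            "icd10_suspected": 300,
            "medication": 250,
            "procedure": 300,
        }
    )
    noise_beta: tuple[float, float] = (0.3, 30.0)
    basal_insulin_codes: tuple[str, ...] = DEFAULT_BASAL_INSULIN_CODES
    insulin_codes: tuple[str, ...] = DEFAULT_INSULIN_CODES
    chart_review_error: float = 0.0
    training_window: DateWindow = TRAINING_WINDOW
    test_window: DateWindow = TEST_WINDOW
    seed: int = 0

    def class_priors(self) -> np.ndarray:
        p1, p2 = self.t1d_prevalence, self.hemophilia_prevalence
        return np.array([1.0 - p1 - p2, p1, p2])

    def validate(self) -> "SimulationConfig":
        if self.n_train < 0 or self.n_test < 0 or self.n_train + self.n_test <= 0:
            raise ConfigError("need a positive number of patients")
        probs = [self.t1d_prevalence, self.hemophilia_prevalence, self.male_fraction,
                 self.chart_review_error]
        for e in self.emission_table:
            probs.extend(e.probs())
        for r in (self.cpr_measured, self.antibody_measured, self.gad_positive,
                  self.ia2_positive, self.referral):
            probs.extend(r.as_array())
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.t1d_prevalence + self.hemophilia_prevalence > 1:
            raise ConfigError("class prevalences exceed 1")
        codes = [(e.system, e.code) for e in self.emission_table]
        if len(set(codes)) != len(codes):
            raise ConfigError("duplicate (system, code) in emission table")
        return self

    def require_codes(self, definitions: list[CaseDefinition]) -> None:
        """Raise unless every definition leaf code is covered by the table."""
        table = {(e.system, e.code) for e in self.emission_table}
        for d in definitions:
            for leaf in d.leaves():
                for code in leaf.codes:
                    if leaf.match == "exact":
                        ok = (leaf.system, code) in table
                    else:
                        ok = any(
                            s == leaf.system and c.startswith(code) for s, c in table
                        )
                    if not ok:
                        raise ConfigError(
                            f"definition {d.name!r} references ({leaf.system}, {code}) "
                            "absent from the emission table"
                        )


def default_emission_table() -> tuple[CodeEmission, ...]:
    """Study-like per-period emission probabilities (background, T1D, hemophilia).

    T1D-class rates for the four definition codes are anchored to the
    published single-code sensitivities (confirmed E10 ≈ 33%, injector
    needles ≈ 33%, any basal insulin ≈ 40%, any CSII pump ≈ 4%); background
    and hemophilia rates are back-solved from the published single-code
    PPVs (E10 ≈ 33%, needles ≈ 65%, basal ≈ 9%, CSII ≈ 86%) at the default
    prevalences.
    """
    E = CodeEmission
    return (
        # diagnoses
        E("icd10_confirmed", "E10", 0.0027, 0.33, 0.0027),
        E("icd10_suspected", "E10", 0.003, 0.25, 0.003),
        E("icd10_confirmed", "E11", 0.05, 0.04, 0.05),
        E("icd10_suspected", "E11", 0.08, 0.06, 0.08),
        E("icd10_confirmed", "E14", 0.004, 0.10, 0.004),
        E("icd10_confirmed", KETOACIDOSIS_CODE, 0.002, 0.15, 0.002),
        E("icd10_confirmed", "D66", 0.0001, 0.0001, 0.90),
        # medications (generic-name codes)
        E("medication", "insulin_glargine", 0.00823, 0.2254, 0.00823),
        E("medication", "insulin_nph", 0.00823, 0.2254, 0.00823),
        E("medication", "insulin_detemir", 0.0, 0.0, 0.0),
        E("medication", "insulin_degludec", 0.0, 0.0, 0.0),
        E("medication", "insulin_biphasic_aspart", 0.0, 0.0, 0.0),
        E("medication", "insulin_aspart", 0.01, 0.50, 0.01),
        # procedures
        E("procedure", "114010970", 0.0001, 0.33, 0.36),  # injector needles
        E("procedure", "114004810", 1.3e-5, 0.030, 1.3e-5),  # CSII pump
        E("procedure", "114022010", 1.3e-5, 0.0103, 1.3e-5),  # CSII pump
        E("procedure", "160010010", 0.08, 0.95, 0.08),  # HbA1c test
        E("procedure", "160151050", 0.001, 0.45, 0.001),  # glucometer supply
        E("procedure", "114015610", 0.005, 0.30, 0.005),  # glycoalbumin test
        E("procedure", INSULIN_RECEPTOR_AB_TEST_CODE, 0.001, 0.10, 0.001),
        E("procedure", PANCREAS_TRANSPLANT_CODE, 1e-5, 0.008, 1e-5),
    )


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(emission_table=default_emission_table())
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg.validate()


# --- generation ------------------------------------------------------------

_NOISE_EXCLUDED_ICD_PREFIXES = ("E10", "E11", "E13", "E14", "E87", "D66")


def _noise_catalogue(config: SimulationConfig, rng: np.random.Generator):
    """Deterministic catalogue of class-independent (system, code, prob)."""
    systems, codes = [], []
    for system, n in config.noise_codes.items():
        made = 0
        i = 0
        signal = {e.code for e in config.emission_table if e.system == system}
        while made < n:
            if system.startswith("icd10"):
                code = f"{chr(65 + i % 26)}{i // 26:02d}"
            elif system == "medication":
                code = f"med{i:04d}"
            else:
                code = f"16{i:07d}"
            i += 1
            if code in signal or code.startswith(_NOISE_EXCLUDED_ICD_PREFIXES):
                continue
            systems.append(system)
            codes.append(code)
            made += 1
    a, b = config.noise_beta
    probs = rng.beta(a, b, size=len(codes))
    return systems, codes, probs


def _uniform_dates(
    rng: np.random.Generator, window: DateWindow, n: int
) -> np.ndarray:
    days = (window.end - window.start).days
    offs = rng.integers(0, days, size=n)
    base = np.datetime64(window.start)
    return (base + offs.astype("timedelta64[D]")).astype("datetime64[D]")


def _rate(r: ClassRates, latent: np.ndarray) -> np.ndarray:
    return r.as_array()[latent]


def _simulate_group(
    config: SimulationConfig,
    n: int,
    prefix: str,
    window: DateWindow,
    period: str,
    rng: np.random.Generator,
    noise: tuple,
) -> tuple[StudyDataset, pd.DataFrame]:
    latent = rng.choice(3, size=n, p=config.class_priors())
    pids = np.array([f"{prefix}{i:07d}" for i in range(n)])

    # demographics
    means = np.array([config.age_mean_sd[c][0] for c in CLASSES])[latent]
    sds = np.array([config.age_mean_sd[c][1] for c in CLASSES])[latent]
    age = np.clip(np.round(rng.normal(means, sds)), 0, 100).astype(int)
    birth_year = window.start.year - age
    male = rng.random(n) < config.male_fraction
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": np.where(male, "male", "female"),
            "birth_year": birth_year,
        }
    )

    ev_pid, ev_system, ev_code = [], [], []

    def emit(mask: np.ndarray, system: str, code: str) -> None:
        idx = np.nonzero(mask)[0]
        if len(idx):
            ev_pid.append(pids[idx])
            ev_system.append(np.repeat(system, len(idx)))
            ev_code.append(np.repeat(code, len(idx)))

    for e in config.emission_table:
        emit(rng.random(n) < e.probs()[latent], e.system, e.code)

    # CPR measurement: procedure code + lab value
    cpr_mask = rng.random(n) < _rate(config.cpr_measured, latent)
    emit(cpr_mask, "procedure", CPR_TEST_CODE)
    mus = np.array([config.cpr_lognormal[c][0] for c in CLASSES])[latent]
    sigmas = np.array([config.cpr_lognormal[c][1] for c in CLASSES])[latent]
    cpr_values = np.exp(rng.normal(mus, sigmas))

    # autoantibodies
    ab_mask = rng.random(n) < _rate(config.antibody_measured, latent)
    gad_pos = rng.random(n) < _rate(config.gad_positive, latent)
    ia2_pos = rng.random(n) < _rate(config.ia2_positive, latent)

    referral = rng.random(n) < _rate(config.referral, latent)

    # class-independent noise codes, drawn in blocks to bound memory
    noise_systems, noise_codes, noise_probs = noise
    block = 64
    for start in range(0, len(noise_codes), block):
        stop = min(start + block, len(noise_codes))
        draws = rng.random((n, stop - start)) < noise_probs[start:stop]
        rows, cols = np.nonzero(draws)
        for j in range(stop - start):
            sel = rows[cols == j]
            if len(sel):
                ev_pid.append(pids[sel])
                ev_system.append(np.repeat(noise_systems[start + j], len(sel)))
                ev_code.append(np.repeat(noise_codes[start + j], len(sel)))

    if ev_pid:
        all_pid = np.concatenate(ev_pid)
        events = pd.DataFrame(
            {
                "patient_id": all_pid,
                "date": _uniform_dates(rng, window, len(all_pid)),
                "system": np.concatenate(ev_system),
                "code": np.concatenate(ev_code),
            }
        )
        events["date"] = pd.Series(events["date"]).astype("datetime64[s]").dt.date
    else:
        events = pd.DataFrame(columns=["patient_id", "date", "system", "code"])

    lab_frames = []
    cpr_idx = np.nonzero(cpr_mask)[0]
    if len(cpr_idx):
        lab_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids[cpr_idx],
                    "date": pd.Series(
                        _uniform_dates(rng, window, len(cpr_idx))
                    ).astype("datetime64[s]").dt.date,
                    "test": "serum_cpr",
                    "value": np.round(cpr_values[cpr_idx], 3),
                }
            )
        )
    ab_idx = np.nonzero(ab_mask)[0]
    for test, pos in (("gad_antibody", gad_pos), ("ia2_antibody", ia2_pos)):
        if len(ab_idx):
            lab_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[ab_idx],
                        "date": pd.Series(
                            _uniform_dates(rng, window, len(ab_idx))
                        ).astype("datetime64[s]").dt.date,
                        "test": test,
                        "value": pos[ab_idx].astype(float),
                    }
                )
            )
    labs = (
        pd.concat(lab_frames, ignore_index=True)
        if lab_frames
        else pd.DataFrame(columns=["patient_id", "date", "test", "value"])
    )

    flags = pd.DataFrame(
        {
            "patient_id": pids,
            "diabetologist_referral": referral,
            "chart_review_verdict": "not_reviewed",
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "latent_t1d": latent == 1,
            "latent_hemophilia": latent == 2,
        }
    )
    ds = StudyDataset(
        patients=patients, events=events, labs=labs, flags=flags, period=period
    )
    return ds, truth


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[StudyDataset, StudyDataset, pd.DataFrame]:
    """Generate disjoint training- and test-period datasets plus ground truth.

    Training patients visit only during the training window and test
    patients only during the test window, matching the study split rule
    (test patients must be unseen during the training period).
    Deterministic given ``seed`` (defaults to ``config.seed``).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    cat_ss, train_ss, test_ss = ss.spawn(3)
    noise = _noise_catalogue(config, np.random.default_rng(cat_ss))
    train, truth_train = _simulate_group(
        config, config.n_train, "TR", config.training_window, "training",
        np.random.default_rng(train_ss), noise,
    )
    test, truth_test = _simulate_group(
        config, config.n_test, "TE", config.test_window, "test",
        np.random.default_rng(test_ss), noise,
    )
    truth = pd.concat([truth_train, truth_test], ignore_index=True)
    return train, test, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[["patient_id", "latent_t1d", "latent_hemophilia"]].to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["latent_t1d"] = df["latent_t1d"].astype(bool)
    df["latent_hemophilia"] = df["latent_hemophilia"].astype(bool)
    return df


# --- oracles ----------------------------------------------------------------

@dataclass(frozen=True)
class ClassicalPerformance:
    """Classical 2×2 confusion against latent truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ppv(self) -> float | None:
        """None when the definition matches nobody (undefined ratio)."""
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None


def true_definition_performance(
    definition: CaseDefinition, dataset: StudyDataset, truth: pd.DataFrame
) -> ClassicalPerformance:
    """Exact confusion of a definition against latent T1D status."""
    ids = dataset.patient_ids()
    covered = set(truth["patient_id"])
    if not ids <= covered:
        missing = sorted(ids - covered)[:5]
        raise ReferenceError(f"patients missing from truth: {missing} …")
    pos = positive_ids(definition, dataset.events)
    t1d = set(truth.loc[truth["latent_t1d"], "patient_id"]) & ids
    tp = len(pos & t1d)
    fp = len(pos - t1d)
    fn = len(t1d - pos)
    tn = len(ids) - tp - fp - fn
    return ClassicalPerformance(tp=tp, fp=fp, fn=fn, tn=tn)


def _signal_code_list(config: SimulationConfig) -> list[tuple[str, str, np.ndarray]]:
    out = [(e.system, e.code, e.probs()) for e in config.emission_table]
    out.append(("procedure", CPR_TEST_CODE, config.cpr_measured.as_array()))
    return out


def calibrated_scores(dataset: StudyDataset, config: SimulationConfig) -> pd.DataFrame:
    """Exact posterior P(T1D | observed class-dependent codes) per patient.

    Because codes are conditionally independent Bernoulli given the latent
    class, Bayes' rule over the three classes is exact.  Noise codes have
    identical emission probabilities in every class and cancel, so only the
    emission-table codes (plus the CPR-test procedure code) enter.  Returns
    ``patient_id, p_case`` with ``p_case`` the T1D posterior.
    """
    signal = _signal_code_list(config)
    pids = dataset.patients["patient_id"].to_numpy()
    order = pd.Series(np.arange(len(pids)), index=pids)
    ev = dataset.events
    X = np.zeros((len(pids), len(signal)))
    for j, (system, code, _) in enumerate(signal):
        hit = ev.loc[(ev["system"] == system) & (ev["code"] == code), "patient_id"]
        if len(hit):
            X[order[hit.unique()].to_numpy(), j] = 1.0
    E = np.clip(np.array([p for _, _, p in signal]), 1e-12, 1 - 1e-12)  # (k, 3)
    loglik = X @ np.log(E) + (1 - X) @ np.log(1 - E)  # (n, 3)
    loglik += np.log(config.class_priors())
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame({"patient_id": pids, "p_case": post[:, 1]})


def analytic_definition_performance(
    config: SimulationConfig, definition: CaseDefinition
) -> dict:
    """Exact large-sample sensitivity/PPV of a definition under the generator.

    Enumerates the joint distribution of the (few) emission-table codes the
    definition references, per latent class, and integrates the boolean
    expression — an independent closed-form oracle for parameter-recovery
    and coverage tests.
    """
    leaves = definition.leaves()
    involved: list[tuple[str, str, np.ndarray]] = []
    for e in config.emission_table:
        if any(l.matches_code(e.system, e.code) for l in leaves):
            involved.append((e.system, e.code, e.probs()))
    if not involved:
        raise ConfigError(f"definition {definition.name!r} matches no table code")
    k = len(involved)
    p_pos = np.zeros(3)
    for assign in itertools.product((0, 1), repeat=k):
        present = {
            (s, c) for (s, c, _), x in zip(involved, assign) if x
        }

        def ev(node) -> bool:
            if isinstance(node, CodePredicate):
                return any(node.matches_code(s, c) for s, c in present)
            vals = [ev(ch) for ch in node.children]
            return all(vals) if isinstance(node, And) else any(vals)

        if not ev(definition.expr):
            continue
        prob = np.ones(3)
        for (_, _, probs), x in zip(involved, assign):
            prob *= probs if x else 1 - probs
        p_pos += prob
    priors = config.class_priors()
    p_match = float(priors @ p_pos)
    sens = float(p_pos[1])
    ppv = float(priors[1] * p_pos[1] / p_match) if p_match > 0 else None
    return {"sensitivity": sens, "ppv": ppv, "p_positive": p_match}
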