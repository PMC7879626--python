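"""Gold-standard training cohort: screening, adjudication, exclusions, controls.

Possible T1D cases are screened from the training data by five criteria:

1. a confirmed diagnosis code of T1D / insulin-dependent diabetes;
2. insulin prescription AND minimum serum CPR < 0.6 ng/ml AND a
   ketoacidosis diagnosis;
3. a positive GAD or IA2 autoantibody;
4. introduced as definite T1D by a diabetologist (referral flag);
5. minimum serum CPR < 0.2 ng/ml.

Screened patients are adjudicated (chart review in the real study; a
truth-based oracle with an optional error rate here).  Adjudicated cases
lose patients with a pancreas-transplant procedure or any confirmed or
suspected type-2-diabetes code.  Controls are sampled from never-reviewed
patients carrying no confirmed or suspected T1D code, at a configurable
control:case ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import StudyDataset
from .simulate import KETOACIDOSIS_CODE, PANCREAS_TRANSPLANT_CODE, DEFAULT_INSULIN_CODES

CRITERIA = ("c1", "c2", "c3", "c4", "c5")

CPR_THRESHOLD_C2 = 0.6  # ng/ml, strict "less than"
CPR_THRESHOLD_C5 = 0.2


class CohortError(ValueError):
    pass


@dataclass
class CohortConfig:
    #: confirmed diagnosis codes counted as T1D / insulin-dependent diabetes
    t1d_confirmed_codes: tuple[str, ...] = ("E10",)
    #: confirmed/suspected codes triggering the T2D case exclusion
    t2d_codes: tuple[str, ...] = ("E11",)
    ketoacidosis_codes: tuple[str, ...] = (KETOACIDOSIS_CODE,)
    transplant_codes: tuple[str, ...] = (PANCREAS_TRANSPLANT_CODE,)
    insulin_codes: tuple[str, ...] = DEFAULT_INSULIN_CODES
    #: controls sampled per case (69023 / 296 ≈ 233 in the source study)
    control_ratio: float = 233.0
    chart_review_error: float = 0.0


def _ids_with_code(
    events: pd.DataFrame, systems: tuple[str, ...], prefixes: tuple[str, ...]
) -> set[str]:
    sel = events["system"].isin(systems)
    codes = events.loc[sel, "code"].astype(str)
    hit = pd.Series(False, index=codes.index)
    for p in prefixes:
        hit |= codes.str.startswith(p)
    return set(events.loc[sel, "patient_id"][hit])


def screen_possible_cases(
    dataset: StudyDataset, config: CohortConfig | None = None
) -> dict[str, set[str]]:
    """Map patient_id → matched criteria subset (patients matching ≥1)."""
    config = config or CohortConfig()
    ev, labs, flags = dataset.events, dataset.labs, dataset.flags

    c1 = _ids_with_code(ev, ("icd10_confirmed",), config.t1d_confirmed_codes)

    insulin = _ids_with_code(ev, ("medication",), config.insulin_codes)
    keto = _ids_with_code(ev, ("icd10_confirmed",), config.ketoacidosis_codes)
    if len(labs):
        cpr = labs[labs["test"] == "serum_cpr"]
        min_cpr = cpr.groupby("patient_id")["value"].min()
        low_06 = set(min_cpr.index[min_cpr < CPR_THRESHOLD_C2])
        low_02 = set(min_cpr.index[min_cpr < CPR_THRESHOLD_C5])
        ab = labs[labs["test"].isin(("gad_antibody", "ia2_antibody"))]
        c3 = set(ab.loc[ab["value"] == 1, "patient_id"])
    else:
        low_06, low_02, c3 = set(), set(), set()
    c2 = insulin & low_06 & keto
    c5 = low_02
    c4 = (
        set(flags.loc[flags["diabetologist_referral"].astype(bool), "patient_id"])
        if len(flags)
        else set()
    )

    out: dict[str, set[str]] = {}
    for name, ids in zip(CRITERIA, (c1, c2, c3, c4, c5)):
        for pid in ids:
            out.setdefault(pid, set()).add(name)
    return out


def adjudicate(
    possible_cases: dict[str, set[str]],
    truth: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Chart-review verdict per screened patient: ``true_t1d`` / ``not_t1d``.

    With latent ``truth`` the verdict is the truth XOR a Bernoulli
    ``error_rate`` flip (seeded); with chart-review ``flags`` the recorded
    verdicts are taken as-is.
    """
    pids = sorted(possible_cases)
    if truth is not None:
        t = truth.set_index("patient_id")["latent_t1d"]
        missing = [p for p in pids if p not in t.index]
        if missing:
            raise CohortError(f"no truth for screened patients {missing[:5]} …")
        base = t.loc[pids].to_numpy(dtype=bool)
    elif flags is not None:
        v = flags.set_index("patient_id")["chart_review_verdict"]
        missing = [p for p in pids if p not in v.index or v[p] == "not_reviewed"]
        if missing:
            raise CohortError(f"no recorded verdict for {missing[:5]} …")
        base = (v.loc[pids] == "true_t1d").to_numpy()
    else:
        raise CohortError("need either latent truth or chart-review flags")
    flip = np.random.default_rng(seed).random(len(pids)) < error_rate
    verdict = base ^ flip
    return {
        p: ("true_t1d" if ok else "not_t1d") for p, ok in zip(pids, verdict)
    }


def build_cases(
    verdicts: dict[str, str],
    dataset: StudyDataset,
    config: CohortConfig | None = None,
) -> tuple[set[str], dict[str, str]]:
    """Adjudicated cases minus transplant / type-2-diabetes exclusions.

    Returns (case ids, excluded-case id → reason).
    """
    config = config or CohortConfig()
    adjudicated = {p for p, v in verdicts.items() if v == "true_t1d"}
    transplant = _ids_with_code(dataset.events, ("procedure",), config.transplant_codes)
    t2d = _ids_with_code(
        dataset.events, ("icd10_confirmed", "icd10_suspected"), config.t2d_codes
    )
    excluded: dict[str, str] = {}
    for pid in adjudicated & transplant:
        excluded[pid] = "pancreas_transplant"
    for pid in (adjudicated & t2d) - set(excluded):
        excluded[pid] = "t2d_code"
    return adjudicated - set(excluded), excluded


def sample_controls(
    dataset: StudyDataset,
    reviewed_ids: set[str],
    n_cases: int,
    ratio: float,
    seed: int = 0,
) -> set[str]:
    """Random controls from never-reviewed patients with no T1D code.

    Pool = patients not chart-reviewed and carrying neither a confirmed nor
    a suspected T1D code; a simple random sample without replacement of
    size min(pool, ratio × n_cases), deterministic given the seed.
    """
    if ratio <= 0:
        raise CohortError("control ratio must be positive")
    t1d_coded = _ids_with_code(
        dataset.events,
        ("icd10_confirmed", "icd10_suspected"),
        CohortConfig().t1d_confirmed_codes,
    )
    pool = sorted(dataset.patient_ids() - reviewed_ids - t1d_coded)
    if not pool:
        raise CohortError("empty control pool")
    k = min(len(pool), int(round(ratio * n_cases)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    return {pool[i] for i in chosen}


def build_cohort(
    dataset: StudyDataset,
    truth: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run screening → adjudication → exclusions → control sampling.

    Returns one row per labeled patient: ``patient_id, status,
    matched_criteria, exclusion_reason`` with status in
    {case, control, excluded_case}.
    """
    config = config or CohortConfig()
    possible = screen_possible_cases(dataset, config)
    verdicts = adjudicate(
        possible,
        truth=truth,
        flags=flags,
        error_rate=config.chart_review_error,
        seed=seed,
    )
    cases, excluded = build_cases(verdicts, dataset, config)
    controls = sample_controls(
        dataset, reviewed_ids=set(possible), n_cases=len(cases),
        ratio=config.control_ratio, seed=seed + 1,
    )
    rows = []
    for pid in sorted(cases):
        rows.append((pid, "case", "|".join(sorted(possible[pid])), ""))
    for pid, reason in sorted(excluded.items()):
        rows.append((pid, "excluded_case", "|".join(sorted(possible[pid])), reason))
    for pid in sorted(controls):
        rows.append((pid, "control", "", ""))
    return pd.DataFrame(
        rows, columns=["patient_id", "status", "matched_criteria", "exclusion_reason"]
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
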