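"""Probabilistic confusion matrix, performance indexes and bootstrap CIs.

Instead of adjudicating every definition-positive patient, each test
patient carries a predicted probability of being a true case.  Summing
those probabilities yields a real-valued confusion matrix:

* TPs = Σ p over definition-positive patients
* FPs = Σ (1 − p) over definition-positive patients
* FNs = Σ p over definition-negative patients
* TNs = Σ (1 − p) over definition-negative patients

from which sensitivity = TPs/(TPs+FNs), specificity = TNs/(FPs+TNs),
PPV = TPs/(TPs+FPs), NPV = TNs/(FNs+TNs) and
F = 2·sensitivity·PPV/(sensitivity+PPV).  Confidence intervals come from
patient-level bootstrap resampling (percentile method).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import StudyDataset
from .definitions import CaseDefinition, positive_ids

logger = logging.getLogger(__name__)

INDEXES = ("sensitivity", "specificity", "ppv", "npv", "f_score")


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ProbabilisticConfusion:
    tps: float
    fps: float
    fns: float
    tns: float

    @property
    def n_positive(self) -> int:
        return int(round(self.tps + self.fps))

    @property
    def n_total(self) -> float:
        return self.tps + self.fps + self.fns + self.tns


@dataclass
class PerformanceEstimate:
    """Point indexes (proportion scale) with optional per-index CIs.

    An index with a zero denominator is ``None`` ("undefined"), never a
    silent NaN.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f_score: float | None
    n_positive: int = 0
    prevalence_pct: float = float("nan")
    ci: dict = field(default_factory=dict)  # index -> (lower, upper)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INDEXES}


def _score_arrays(scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pids = scores["patient_id"].to_numpy()
    p = scores["p_case"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise MetricsError("probabilities must lie in [0, 1]")
    return pids, p


def probabilistic_confusion(
    scores: pd.DataFrame, positives: set[str]
) -> ProbabilisticConfusion:
    """Cumulative TPs/FPs/FNs/TNs from scores and a definition-positive set."""
    pids, p = _score_arrays(scores)
    known = set(pids)
    if not positives <= known:
        missing = sorted(positives - known)[:5]
        raise MetricsError(f"definition-positive patients without scores: {missing} …")
    pos = (
        np.isin(pids, np.array(sorted(positives)))
        if positives
        else np.zeros(len(pids), dtype=bool)
    )
    return _confusion_from_arrays(p, pos)


def _confusion_from_arrays(p: np.ndarray, pos: np.ndarray) -> ProbabilisticConfusion:
    return ProbabilisticConfusion(
        tps=float(p[pos].sum()),
        fps=float((1.0 - p[pos]).sum()),
        fns=float(p[~pos].sum()),
        tns=float((1.0 - p[~pos]).sum()),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def f_score(sensitivity: float | None, ppv: float | None) -> float | None:
    """Harmonic mean 2·s·p/(s+p) of proportion-scale sensitivity and PPV."""
    if sensitivity is None or ppv is None or sensitivity + ppv == 0:
        return None
    return 2 * sensitivity * ppv / (sensitivity + ppv)


def performance_indexes(
    confusion: ProbabilisticConfusion, n_total_patients: int | None = None
) -> PerformanceEstimate:
    """The five indexes from a probabilistic confusion matrix."""
    if confusion.n_total == 0:
        raise MetricsError("all-zero confusion matrix")
    sens = _ratio(confusion.tps, confusion.tps + confusion.fns)
    spec = _ratio(confusion.tns, confusion.fps + confusion.tns)
    ppv = _ratio(confusion.tps, confusion.tps + confusion.fps)
    npv = _ratio(confusion.tns, confusion.fns + confusion.tns)
    n_total = n_total_patients if n_total_patients else confusion.n_total
    return PerformanceEstimate(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f_score=f_score(sens, ppv),
        n_positive=confusion.n_positive,
        prevalence_pct=100.0 * confusion.n_positive / n_total if n_total else float("nan"),
    )


def _indexes_vectorised(
    tps: np.ndarray, fps: np.ndarray, fns: np.ndarray, tns: np.ndarray
) -> dict[str, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = tps / (tps + fns)
        spec = tns / (fps + tns)
        ppv = tps / (tps + fps)
        npv = tns / (fns + tns)
        f = 2 * sens * ppv / (sens + ppv)
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
            "f_score": f}


def bootstrap_cis(
    scores: pd.DataFrame,
    positives: set[str],
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    chunk: int = 50,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for the five indexes.

    Test patients are resampled with replacement as (score, definition
    status) pairs; each replicate recomputes all indexes.  Replicates where
    an index is undefined are dropped for that index (with a logged count).
    Deterministic given the seed.
    """
    if n_reps < 1:
        raise MetricsError("n_reps must be ≥ 1")
    if not 0 < level < 1:
        raise MetricsError("level must lie in (0, 1)")
    pids, p = _score_arrays(scores)
    known = set(pids)
    if not positives <= known:
        raise MetricsError("definition-positive patients without scores")
    pos = (
        np.isin(pids, np.array(sorted(positives)))
        if positives
        else np.zeros(len(pids), dtype=bool)
    )
    n = len(p)
    p_pos = p * pos
    p_neg = p * ~pos
    q_pos = (1.0 - p) * pos
    q_neg = (1.0 - p) * ~pos

    rng = np.random.default_rng(seed)
    reps: dict[str, list[np.ndarray]] = {k: [] for k in INDEXES}
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        idx = rng.integers(0, n, size=(m, n))
        tps = p_pos[idx].sum(axis=1)
        fps = q_pos[idx].sum(axis=1)
        fns = p_neg[idx].sum(axis=1)
        tns = q_neg[idx].sum(axis=1)
        vals = _indexes_vectorised(tps, fps, fns, tns)
        for k in INDEXES:
            reps[k].append(vals[k])
        done += m

    alpha = (1.0 - level) / 2.0
    out: dict[str, tuple[float, float] | None] = {}
    for k in INDEXES:
        v = np.concatenate(reps[k])
        defined = v[np.isfinite(v)]
        dropped = len(v) - len(defined)
        if dropped:
            logger.info("bootstrap: %d/%d replicates undefined for %s", dropped, len(v), k)
        if not len(defined):
            # an index that is undefined in every replicate (e.g. NPV when
            # everyone matches the definition) gets no interval
            logger.warning("bootstrap: %s undefined in every replicate", k)
            out[k] = None
            continue
        out[k] = (
            float(np.quantile(defined, alpha)),
            float(np.quantile(defined, 1.0 - alpha)),
        )
    if all(v is None for v in out.values()):
        raise MetricsError("every bootstrap replicate undefined for every index")
    return out


def evaluate_definition(
    scores: pd.DataFrame,
    positives: set[str],
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> PerformanceEstimate:
    """Point indexes plus bootstrap CIs for one definition-positive set."""
    est = performance_indexes(probabilistic_confusion(scores, positives))
    if n_reps:
        est.ci = bootstrap_cis(scores, positives, n_reps=n_reps, level=level, seed=seed)
    return est


def evaluate_all(
    scores: pd.DataFrame,
    definitions: Sequence[CaseDefinition],
    dataset: StudyDataset,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """One report row per definition (N, prevalence %, indexes with CIs).

    Sensitivity/PPV/specificity/NPV are reported on the percentage scale,
    the F-score as a proportion — the reporting convention of the field.
    """
    missing = dataset.patient_ids() - set(scores["patient_id"])
    if missing:
        raise MetricsError(f"{len(missing)} test patients lack scores")
    rows = []
    for i, d in enumerate(definitions):
        positives = positive_ids(d, dataset.events) & dataset.patient_ids()
        try:
            est = evaluate_definition(
                scores, positives, n_reps=n_reps, level=level, seed=seed + i
            )
        except MetricsError as exc:
            logger.warning("definition %s: %s", d.name, exc)
            rows.append({"definition": d.name, "n": len(positives), "note": str(exc)})
            continue
        pct = lambda x: 100.0 * x if x is not None else None
        row = {
            "definition": d.name,
            "n": len(positives),
            "prevalence_pct": 100.0 * len(positives) / dataset.n_patients,
            "sensitivity_pct": pct(est.sensitivity),
            "ppv_pct": pct(est.ppv),
            "f_score": est.f_score,
            "specificity_pct": pct(est.specificity),
            "npv_pct": pct(est.npv),
            "note": "",
        }
        for k in INDEXES:
            if est.ci.get(k) is not None:
                lo, hi = est.ci[k]
                scale = 1.0 if k == "f_score" else 100.0
                row[f"{k}_lo"] = scale * lo
                row[f"{k}_hi"] = scale * hi
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> pd.DataFrame:
    """Printed report: percentages at 1 dp, F-score at 3 dp, with CIs."""

    def fmt(row, key, dp):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "undefined"
        lo, hi = row.get(f"{key.replace('_pct', '')}_lo"), row.get(
            f"{key.replace('_pct', '')}_hi"
        )
        s = f"{v:.{dp}f}"
        if lo is not None and not math.isnan(lo):
            s += f" ({lo:.{dp}f}, {hi:.{dp}f})"
        return s

    out = []
    for _, row in table.iterrows():
        r = row.to_dict()
        out.append(
            {
                "definition": r["definition"],
                "n_pct": f"{r['n']} ({r.get('prevalence_pct', float('nan')):.3f})",
                "sensitivity": fmt(r, "sensitivity_pct", 1),
                "ppv": fmt(r, "ppv_pct", 1),
                "f_score": fmt(r, "f_score", 3),
                "specificity": fmt(r, "specificity_pct", 1),
                "npv": fmt(r, "npv_pct", 1),
            }
        )
    return pd.DataFrame(out)
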