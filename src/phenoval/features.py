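"""Binary feature matrix from coded events, with relative-risk screening.

Each (namespace, code) pair observed in a dataset becomes one 0/1 dummy —
"the patient had the code at least once during the period".  Diagnoses are
truncated to their first three ICD-10 characters and keep their
confirmed/suspected namespace; medication codes are mapped to generic
names.  Features used to build the gold standard (confirmed T1D/T2D/
ketoacidosis, T1D/T2D-related suspected codes, insulin medications, CPR
and insulin-receptor-autoantibody test codes) leak the label and are
removed via a :class:`LeakageList` of glob patterns.

Screening ranks features by the relative risk of case status given feature
presence and keeps the top *k* (default 500); age and sex always bypass
the screen.
"""

from __future__ import annotations

import fnmatch
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import StudyDataset, ages_at
from .simulate import (
    CPR_TEST_CODE,
    DEFAULT_INSULIN_CODES,
    INSULIN_RECEPTOR_AB_TEST_CODE,
)

logger = logging.getLogger(__name__)

ALWAYS_KEPT = ("age", "sex")

_NAMESPACE = {
    "icd10_confirmed": "confirmed",
    "icd10_suspected": "suspected",
    "medication": "med",
    "procedure": "proc",
}

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}")


class FeatureError(ValueError):
    pass


def truncate_icd10(code: str) -> str:
    """First three characters of an ICD-10 code (``E101`` → ``E10``)."""
    if not _ICD_RE.match(str(code)):
        raise FeatureError(f"malformed ICD-10 code: {code!r}")
    return str(code)[:3]


@dataclass(frozen=True)
class LeakageList:
    """Feature-name glob patterns excluded from the model."""

    patterns: tuple[str, ...]

    def matches(self, name: str) -> bool:
        return any(fnmatch.fnmatchcase(name, p) for p in self.patterns)

    def filter(self, names: list[str]) -> list[str]:
        return [n for n in names if not self.matches(n)]


def default_leakage(
    insulin_generics: tuple[str, ...] = DEFAULT_INSULIN_CODES,
) -> LeakageList:
    """Gold-standard-derived features that must not enter the model."""
    patterns = [
        "confirmed:E10",  # T1D
        "confirmed:E11",  # T2D
        "confirmed:E87",  # ketoacidosis
        "suspected:E10",
        "suspected:E11",
        "suspected:E13",
        "suspected:E14",
        f"proc:{CPR_TEST_CODE}",
        f"proc:{INSULIN_RECEPTOR_AB_TEST_CODE}",
    ]
    patterns += [f"med:{g}" for g in insulin_generics]
    return LeakageList(tuple(patterns))


@dataclass
class FeatureMatrix:
    """Patient × feature table: binary dummies plus numeric age, binary sex."""

    matrix: pd.DataFrame  # index = patient_id, columns = feature names

    @property
    def patient_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)

    def subset(self, names: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.matrix.loc[:, names])


def _feature_name(system: str, code: str, generic_map: dict[str, str]) -> str | None:
    ns = _NAMESPACE[system]
    if ns in ("confirmed", "suspected"):
        try:
            code = truncate_icd10(code)
        except FeatureError:
            logger.warning("dropping malformed ICD-10 code %r", code)
            return None
    elif ns == "med":
        if code in generic_map:
            code = generic_map[code]
        elif generic_map:
            if code not in _warned_unmapped:
                _warned_unmapped.add(code)
                logger.warning(
                    "medication code %r missing from generic map; used verbatim", code
                )
    return f"{ns}:{code}"


_warned_unmapped: set[str] = set()


def build_features(
    dataset: StudyDataset,
    leakage: LeakageList | None = None,
    generic_map: dict[str, str] | None = None,
    reference_year: int | None = None,
) -> FeatureMatrix:
    """One 0/1 column per observed (namespace, code), plus age and sex.

    Column order is deterministic (lexicographic), independent of event-row
    order; leakage-listed columns are dropped.
    """
    leakage = leakage or default_leakage()
    generic_map = generic_map if generic_map is not None else {}
    if reference_year is None:
        reference_year = (
            2015 if dataset.period == "test" else 2009
        )
    pids = dataset.patients["patient_id"].to_numpy()
    index = pd.Index(pids, name="patient_id")
    ev = dataset.events
    names = np.array(
        [
            _feature_name(s, c, generic_map)
            for s, c in zip(ev["system"].to_numpy(), ev["code"].astype(str).to_numpy())
        ],
        dtype=object,
    ) if len(ev) else np.array([], dtype=object)
    keep = np.array([n is not None and not leakage.matches(n) for n in names], bool)
    if keep.any():
        pairs = pd.DataFrame(
            {"patient_id": ev["patient_id"].to_numpy()[keep], "feature": names[keep]}
        ).drop_duplicates()
        wide = (
            pairs.assign(v=np.int8(1))
            .pivot_table(index="patient_id", columns="feature", values="v", fill_value=0)
            .reindex(index, fill_value=0)
            .astype(np.int8)
        )
        wide = wide.loc[:, sorted(wide.columns)]
    else:
        wide = pd.DataFrame(index=index)
    wide.insert(0, "age", ages_at(dataset, reference_year).to_numpy())
    wide.insert(1, "sex", (dataset.patients["sex"] == "male").astype(np.int8).to_numpy())
    wide.columns.name = None
    return FeatureMatrix(wide)


def relative_risk(feature: np.ndarray, labels: np.ndarray) -> float:
    """Relative risk of case status given feature presence vs absence.

    With the 2×2 cells a, b (cases/non-cases with the feature) and c, d
    (without), RR = [a/(a+b)] / [c/(c+d)].  A 0.5 continuity correction on
    all four cells is applied whenever any cell is zero, which keeps the
    statistic finite (and equal to 1 for a feature with no variation).
    """
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if not set(np.unique(feature)) <= {0, 1} or not set(np.unique(labels)) <= {0, 1}:
        raise TypeError("relative_risk expects binary inputs")
    a = int(np.sum((feature == 1) & (labels == 1)))
    b = int(np.sum((feature == 1) & (labels == 0)))
    c = int(np.sum((feature == 0) & (labels == 1)))
    d = int(np.sum((feature == 0) & (labels == 0)))
    if a + b == 0 or c + d == 0:
        return 1.0  # constant feature: no discrimination
    eps = 0.5 if 0 in (a, b, c, d) else 0.0
    risk_with = (a + eps) / (a + b + 2 * eps)
    risk_without = (c + eps) / (c + d + 2 * eps)
    return risk_with / risk_without


def rr_screen(features: FeatureMatrix, labels: pd.Series) -> pd.Series:
    """Relative risk per coded feature (age/sex excluded), vectorised."""
    coded = [n for n in features.feature_names if n not in ALWAYS_KEPT]
    X = features.matrix[coded].to_numpy()
    y = labels.loc[features.matrix.index].to_numpy().astype(np.int8)
    a = (X * y[:, None]).sum(axis=0).astype(float)
    b = (X * (1 - y)[:, None]).sum(axis=0).astype(float)
    c = y.sum() - a
    d = (1 - y).sum() - b
    eps = np.where((a == 0) | (b == 0) | (c == 0) | (d == 0), 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = ((a + eps) / (a + b + 2 * eps)) / ((c + eps) / (c + d + 2 * eps))
    rr = np.where((a + b == 0) | (c + d == 0), 1.0, rr)
    return pd.Series(rr, index=coded, name="relative_risk")


def select_top_k(rr: pd.Series, k: int = 500) -> list[str]:
    """Top-k feature names by RR descending; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    order = sorted(rr.items(), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order[:k]]


def screen_features(
    features: FeatureMatrix, labels: pd.Series, k: int = 500
) -> FeatureMatrix:
    """RR-screen the coded columns, always retaining age and sex."""
    rr = rr_screen(features, labels)
    selected = select_top_k(rr, k)
    kept = [c for c in ALWAYS_KEPT if c in features.feature_names] + selected
    return features.subset(kept)
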