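"""Boolean case definitions over claims codes.

A case definition is an AND/OR expression tree whose leaves are
:class:`CodePredicate` objects — "the patient has ≥1 event in this code
system matching one of these codes" (exact or prefix match).  Negation is
deliberately unsupported: claims-data case definitions in this setting are
monotone in a patient's code set.

The eleven built-in definitions combine four code groups:

* ``E10``        — confirmed ICD-10 diagnosis of type 1 diabetes (prefix match)
* ``114010970``  — injector needles for T1D patients (a code shared with
  hemophilia patients)
* basal insulin  — a configurable medication code list (long-acting,
  intermediate-acting and biphasic preparations)
* ``114004810`` / ``114022010`` — syringe pump for continuous subcutaneous
  insulin infusion (CSII)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import yaml

from .data_model import EVENT_SYSTEMS, StudyDataset

NEEDLE_CODE = "114010970"
CSII_CODES = ("114004810", "114022010")
T1D_CONFIRMED_PREFIX = "E10"


class DefinitionError(ValueError):
    pass


@dataclass(frozen=True)
class CodePredicate:
    """True for a patient with ≥1 event of ``system`` matching ``codes``."""

    system: str
    codes: frozenset[str]
    match: str = "exact"  # or "prefix"

    def __post_init__(self):
        if self.system not in EVENT_SYSTEMS:
            raise DefinitionError(f"unknown system {self.system!r}")
        if not self.codes:
            raise DefinitionError("predicate needs at least one code")
        if self.match not in ("exact", "prefix"):
            raise DefinitionError(f"unknown match mode {self.match!r}")

    def matches_code(self, system: str, code: str) -> bool:
        if system != self.system:
            return False
        if self.match == "exact":
            return code in self.codes
        return any(code.startswith(c) for c in self.codes)


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]

    def __post_init__(self):
        if not self.children:
            raise DefinitionError("AND needs children")


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]

    def __post_init__(self):
        if not self.children:
            raise DefinitionError("OR needs children")


Expr = Union[CodePredicate, And, Or]


@dataclass(frozen=True)
class CaseDefinition:
    name: str
    expr: Expr

    def leaves(self) -> list[CodePredicate]:
        out: list[CodePredicate] = []

        def walk(node: Expr):
            if isinstance(node, CodePredicate):
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.expr)
        return out


def pred(system: str, codes: Iterable[str] | str, match: str = "exact") -> CodePredicate:
    if isinstance(codes, str):
        codes = [codes]
    return CodePredicate(system=system, codes=frozenset(codes), match=match)


def builtin_definitions(basal_insulin_codes: Sequence[str]) -> list[CaseDefinition]:
    """The eleven candidate case definitions, in reporting order.

    With ① = confirmed T1D diagnosis (E10 prefix), ② = injector-needle
    procedure, ③ = any basal-insulin medication, ④ = CSII pump procedure:
    ①; ②; ③; ④; ①∧②; ①∧③; ①∧④; ①∧(③∨④); ①∧(②∨④); ①∧(②∨③); ①∧(②∨③∨④).
    """
    if not basal_insulin_codes:
        raise DefinitionError("basal insulin code list must not be empty")
    d1 = pred("icd10_confirmed", T1D_CONFIRMED_PREFIX, match="prefix")
    d2 = pred("procedure", NEEDLE_CODE)
    d3 = pred("medication", list(basal_insulin_codes))
    d4 = pred("procedure", list(CSII_CODES))
    A, O = lambda *c: And(tuple(c)), lambda *c: Or(tuple(c))
    return [
        CaseDefinition("1_e10", d1),
        CaseDefinition("2_needle", d2),
        CaseDefinition("3_basal_insulin", d3),
        CaseDefinition("4_csii_pump", d4),
        CaseDefinition("5_e10_and_needle", A(d1, d2)),
        CaseDefinition("6_e10_and_basal", A(d1, d3)),
        CaseDefinition("7_e10_and_csii", A(d1, d4)),
        CaseDefinition("8_e10_and_basal_or_csii", A(d1, O(d3, d4))),
        CaseDefinition("9_e10_and_needle_or_csii", A(d1, O(d2, d4))),
        CaseDefinition("10_e10_and_needle_or_basal", A(d1, O(d2, d3))),
        CaseDefinition("11_e10_and_needle_or_basal_or_csii", A(d1, O(d2, d3, d4))),
    ]


def matches(definition: CaseDefinition, patient_events: pd.DataFrame) -> bool:
    """Evaluate one definition against a single patient's events."""
    systems = patient_events["system"].to_numpy()
    codes = patient_events["code"].astype(str).to_numpy()

    def ev(node: Expr) -> bool:
        if isinstance(node, CodePredicate):
            return any(
                node.matches_code(s, c) for s, c in zip(systems, codes)
            )
        if isinstance(node, And):
            return all(ev(c) for c in node.children)
        return any(ev(c) for c in node.children)

    return ev(definition.expr)


def _leaf_positive_ids(leaf: CodePredicate, events: pd.DataFrame) -> set[str]:
    sel = events["system"] == leaf.system
    codes = events.loc[sel, "code"].astype(str)
    if leaf.match == "exact":
        hit = codes.isin(leaf.codes)
    else:
        hit = pd.Series(False, index=codes.index)
        for c in leaf.codes:
            hit |= codes.str.startswith(c)
    return set(events.loc[sel, "patient_id"][hit])


def positive_ids(definition: CaseDefinition, events: pd.DataFrame) -> set[str]:
    """Set of patient ids matching the definition (vectorised over patients)."""

    def ev(node: Expr) -> set[str]:
        if isinstance(node, CodePredicate):
            return _leaf_positive_ids(node, events)
        sets = [ev(c) for c in node.children]
        if isinstance(node, And):
            return set.intersection(*sets)
        return set.union(*sets)

    return ev(definition.expr)


def apply_definitions(
    definitions: Sequence[CaseDefinition], dataset: StudyDataset
) -> pd.DataFrame:
    """Per-definition positive-id sets and prevalence in the dataset.

    Returns one row per definition: name, n (matching patients), pct
    (percentage of dataset patients matching) and the id set itself.
    """
    n_total = dataset.n_patients
    rows = []
    for d in definitions:
        ids = positive_ids(d, dataset.events)
        rows.append(
            {
                "definition": d.name,
                "n": len(ids),
                "pct": 100.0 * len(ids) / n_total if n_total else 0.0,
                "ids": ids,
            }
        )
    return pd.DataFrame(rows)


# --- YAML round-trip -------------------------------------------------------

def _expr_to_obj(node: Expr):
    if isinstance(node, CodePredicate):
        return {
            "system": node.system,
            "codes": sorted(node.codes),
            "match": node.match,
        }
    key = "all" if isinstance(node, And) else "any"
    return {key: [_expr_to_obj(c) for c in node.children]}


def _expr_from_obj(obj) -> Expr:
    if "all" in obj:
        return And(tuple(_expr_from_obj(c) for c in obj["all"]))
    if "any" in obj:
        return Or(tuple(_expr_from_obj(c) for c in obj["any"]))
    return CodePredicate(
        system=obj["system"],
        codes=frozenset(obj["codes"]),
        match=obj.get("match", "exact"),
    )


def save_definitions(definitions: Sequence[CaseDefinition], path: str | Path) -> None:
    obj = [{"name": d.name, "expr": _expr_to_obj(d.expr)} for d in definitions]
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_definitions(path: str | Path) -> list[CaseDefinition]:
    obj = yaml.safe_load(Path(path).read_text())
    return [CaseDefinition(d["name"], _expr_from_obj(d["expr"])) for d in obj]
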