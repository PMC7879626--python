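"""Domain types and delimited-file I/O for claims/EHR study datasets.

A study dataset is four long-format tables:

* ``patients``  — patient_id, sex, birth_year
* ``events``    — patient_id, date, system, code (one coded occurrence per row)
* ``labs``      — patient_id, date, test, value
* ``flags``     — patient_id, diabetologist_referral, chart_review_verdict

Japanese claims distinguish *confirmed* diagnoses from *suspected* ones
(codes attached only to justify a test); the two live in separate code
namespaces (``icd10_confirmed`` vs ``icd10_suspected``) throughout.

Files are UTF-8 CSV with a header row; dates are ISO-8601.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

EVENT_SYSTEMS = ("icd10_confirmed", "icd10_suspected", "medication", "procedure")
LAB_TESTS = ("serum_cpr", "gad_antibody", "ia2_antibody")
VERDICTS = ("true_t1d", "not_t1d", "not_reviewed")
SEXES = ("male", "female")

#: at least a letter followed by two digits, e.g. E10, E872, F50
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")

PATIENT_COLS = ["patient_id", "sex", "birth_year"]
EVENT_COLS = ["patient_id", "date", "system", "code"]
LAB_COLS = ["patient_id", "date", "test", "value"]
FLAG_COLS = ["patient_id", "diabetologist_referral", "chart_review_verdict"]


class DataError(ValueError):
    """Base class for dataset validation failures."""


class SchemaError(DataError):
    """A table is missing a declared column."""


class ParseError(DataError):
    """A row holds a value outside its enumerated/typed domain."""


class ReferentialError(DataError):
    """A row references a patient_id absent from the patient table."""


@dataclass
class StudyDataset:
    """Validated container for one study period's tables.

    ``period`` labels the dataset ("training"/"test"); the tables are
    plain pandas DataFrames with the fixed column orders above.
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    labs: pd.DataFrame
    flags: pd.DataFrame
    period: str = "training"

    def patient_ids(self) -> set[str]:
        return set(self.patients["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _empty(cols: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _bad_rows(mask: pd.Series) -> str:
    rows = list(mask[mask].index[:5])
    return f"rows {rows}" + (" …" if mask.sum() > 5 else "")


def validate_dataset(ds: StudyDataset) -> StudyDataset:
    """Check invariants; raise a row-numbered :class:`DataError` on failure."""
    _require_columns(ds.patients, PATIENT_COLS, "patients")
    _require_columns(ds.events, EVENT_COLS, "events")
    _require_columns(ds.labs, LAB_COLS, "labs")
    _require_columns(ds.flags, FLAG_COLS, "flags")

    if ds.patients["patient_id"].duplicated().any():
        dup = ds.patients["patient_id"].duplicated()
        raise ParseError(f"patients: duplicate patient_id at {_bad_rows(dup)}")
    bad_sex = ~ds.patients["sex"].isin(SEXES)
    if bad_sex.any():
        raise ParseError(f"patients: sex not in {SEXES} at {_bad_rows(bad_sex)}")

    if len(ds.events):
        bad_sys = ~ds.events["system"].isin(EVENT_SYSTEMS)
        if bad_sys.any():
            raise ParseError(
                f"events: unknown system value at {_bad_rows(bad_sys)} "
                f"(allowed: {EVENT_SYSTEMS})"
            )
        icd = ds.events["system"].isin(("icd10_confirmed", "icd10_suspected"))
        bad_code = icd & ~ds.events.loc[:, "code"].astype(str).str.match(ICD10_RE)
        if bad_code.any():
            raise ParseError(f"events: malformed ICD-10 code at {_bad_rows(bad_code)}")
    if len(ds.labs):
        bad_test = ~ds.labs["test"].isin(LAB_TESTS)
        if bad_test.any():
            raise ParseError(f"labs: unknown test at {_bad_rows(bad_test)}")
        vals = pd.to_numeric(ds.labs["value"], errors="coerce")
        cpr = ds.labs["test"] == "serum_cpr"
        bad_cpr = cpr & ((vals < 0) | vals.isna())
        if bad_cpr.any():
            raise ParseError(f"labs: serum_cpr must be ≥ 0 at {_bad_rows(bad_cpr)}")
        bad_ab = ~cpr & ~vals.isin((0.0, 1.0))
        if bad_ab.any():
            raise ParseError(f"labs: antibody value must be 0/1 at {_bad_rows(bad_ab)}")
    if len(ds.flags):
        bad_v = ~ds.flags["chart_review_verdict"].isin(VERDICTS)
        if bad_v.any():
            raise ParseError(f"flags: unknown verdict at {_bad_rows(bad_v)}")

    known = ds.patient_ids()
    for name, df in (("events", ds.events), ("labs", ds.labs), ("flags", ds.flags)):
        if len(df):
            dangling = ~df["patient_id"].isin(known)
            if dangling.any():
                raise ReferentialError(
                    f"{name}: patient_id not in patient table at {_bad_rows(dangling)}"
                )
    return ds


def read_dataset(directory: str | Path, period: str = "training") -> StudyDataset:
    """Read and validate the four CSVs (``patients/events/labs/flags.csv``)."""
    directory = Path(directory)
    dfs = {}
    for name in ("patients", "events", "labs", "flags"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing file: {path}")
        dfs[name] = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    for df in (dfs["events"], dfs["labs"]):
        if len(df):
            df["date"] = pd.to_datetime(df["date"]).dt.date
    if len(dfs["flags"]):
        dfs["flags"]["diabetologist_referral"] = dfs["flags"][
            "diabetologist_referral"
        ].astype(bool)
    ds = StudyDataset(
        patients=dfs["patients"],
        events=dfs["events"] if len(dfs["events"]) else _empty(EVENT_COLS),
        labs=dfs["labs"] if len(dfs["labs"]) else _empty(LAB_COLS),
        flags=dfs["flags"] if len(dfs["flags"]) else _empty(FLAG_COLS),
        period=period,
    )
    return validate_dataset(ds)


def write_dataset(ds: StudyDataset, directory: str | Path) -> None:
    """Write the four CSVs with fixed column order (round-trip stable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds.patients[PATIENT_COLS].to_csv(directory / "patients.csv", index=False)
    ds.events[EVENT_COLS].to_csv(directory / "events.csv", index=False)
    ds.labs[LAB_COLS].to_csv(directory / "labs.csv", index=False)
    ds.flags[FLAG_COLS].to_csv(directory / "flags.csv", index=False)


@dataclass(frozen=True)
class DateWindow:
    """Half-open calendar window [start, end)."""

    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    def contains(self, dates: pd.Series) -> pd.Series:
        return (dates >= self.start) & (dates < self.end)

    def overlaps(self, other: "DateWindow") -> bool:
        return self.start < other.end and other.start < self.end


#: default study windows: train 2009–2014 inclusive, test 2015–2019 inclusive
TRAINING_WINDOW = DateWindow(dt.date(2009, 1, 1), dt.date(2015, 1, 1))
TEST_WINDOW = DateWindow(dt.date(2015, 1, 1), dt.date(2020, 1, 1))


def split_by_period(
    ds: StudyDataset,
    training_window: DateWindow = TRAINING_WINDOW,
    test_window: DateWindow = TEST_WINDOW,
) -> tuple[StudyDataset, StudyDataset]:
    """Split one dataset into disjoint training/test datasets.

    Training patients are those with ≥1 event in the training window (kept
    with their training-window rows only).  Test patients are those with
    *no* event in the training window and ≥1 event in the test window —
    patients seen in both periods are excluded from the test group
    entirely, so the two id sets are disjoint by construction.
    """
    if training_window.overlaps(test_window):
        raise ValueError("training and test windows overlap")
    dates = pd.Series(ds.events["date"])
    in_train = training_window.contains(dates)
    in_test = test_window.contains(dates)
    train_ids = set(ds.events.loc[in_train, "patient_id"])
    test_ids = set(ds.events.loc[in_test, "patient_id"]) - train_ids

    def subset(ids: set[str], window: DateWindow, period: str) -> StudyDataset:
        ev = ds.events[ds.events["patient_id"].isin(ids)]
        ev = ev[window.contains(pd.Series(ev["date"]))]
        labs = ds.labs[ds.labs["patient_id"].isin(ids)]
        if len(labs):
            labs = labs[window.contains(pd.Series(labs["date"]))]
        return StudyDataset(
            patients=ds.patients[ds.patients["patient_id"].isin(ids)].reset_index(
                drop=True
            ),
            events=ev.reset_index(drop=True),
            labs=labs.reset_index(drop=True),
            flags=ds.flags[ds.flags["patient_id"].isin(ids)].reset_index(drop=True),
            period=period,
        )

    return subset(train_ids, training_window, "training"), subset(
        test_ids, test_window, "test"
    )


def ages_at(ds: StudyDataset, reference_year: int) -> pd.Series:
    """Age of every patient at the start of the given window year."""
    return (reference_year - ds.patients["birth_year"]).rename("age")
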