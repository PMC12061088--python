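"""SNDS-like claims event data model: tables, schemas, validation and I/O.

The package works on a :class:`ClaimsDataset`, a container of pandas tables
mirroring the event streams an insurance-claims extract provides:

``persons``
    one row per insured person — ``person_id`` (integer key), ``sex``
    (``male``/``female``), ``birth_year``, optional ``death_date``.
``affiliations``
    half-open coverage intervals ``[start_date, end_date)`` of affiliation
    to the insurance scheme, non-overlapping and ordered per person.
``stays``
    one row per *positioned diagnosis* on a hospital stay: ``stay_id``
    groups the diagnoses of one admission, ``position`` is PD (principal),
    RD (related) or SAD (significant associated), ``icd10_code`` is stored
    without dots.
``ltd_records``
    long-term-disease registrations with their ICD-10 code.
``dispensings``
    drug dispensings: ``drug_id`` is an opaque code resolved to
    ``drug_class`` through a :class:`~mmepi.codes.CodeListConfig` at load.
``procedures``
    lab/medical procedures: ``procedure_code`` resolved to ``kind``
    (SPEP/UPEP/ASCT/other).
``reimbursements``
    billed events of no other modelled kind; together with stays,
    dispensings and procedures they drive the reimbursement-gap censoring.

All dates are day-resolution ``datetime64``; files are RFC-4180 CSV with
ISO-8601 dates, one table per type, plus a ``meta.json`` carrying the
observation window.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codes import CodeListConfig, _ICD10_RE

__all__ = [
    "ClaimsDataset",
    "LoadReport",
    "SchemaError",
    "ReferentialError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "TABLE_FILES",
]


class SchemaError(ValueError):
    """A table violates its documented column schema."""


class ReferentialError(ValueError):
    """An event references a person_id absent from the persons table."""


POSITIONS = ("PD", "RD", "SAD")
SEXES = ("male", "female")

# required columns per table (post-load, classes resolved)
SCHEMAS: dict[str, tuple[str, ...]] = {
    "persons": ("person_id", "sex", "birth_year", "death_date"),
    "affiliations": ("person_id", "start_date", "end_date"),
    "stays": ("person_id", "stay_id", "admission_date", "icd10_code", "position"),
    "ltd_records": ("person_id", "registration_date", "icd10_code"),
    "dispensings": ("person_id", "dispense_date", "drug_id", "drug_class"),
    "procedures": ("person_id", "procedure_date", "procedure_code", "kind"),
    "reimbursements": ("person_id", "event_date"),
}

# columns expected in the on-disk files (derived columns are recomputed)
_FILE_REQUIRED: dict[str, tuple[str, ...]] = {
    "persons": ("person_id", "sex", "birth_year"),
    "affiliations": ("person_id", "start_date", "end_date"),
    "stays": ("person_id", "stay_id", "admission_date", "icd10_code", "position"),
    "ltd_records": ("person_id", "registration_date", "icd10_code"),
    "dispensings": ("person_id", "dispense_date", "drug_id"),
    "procedures": ("person_id", "procedure_date", "procedure_code"),
    "reimbursements": ("person_id", "event_date"),
}

_DATE_COLS: dict[str, tuple[str, ...]] = {
    "persons": ("death_date",),
    "affiliations": ("start_date", "end_date"),
    "stays": ("admission_date",),
    "ltd_records": ("registration_date",),
    "dispensings": ("dispense_date",),
    "procedures": ("procedure_date",),
    "reimbursements": ("event_date",),
}

TABLE_FILES = {name: f"{name}.csv" for name in SCHEMAS}
META_FILE = "meta.json"

EVENT_DATE_COL = {
    "stays": "admission_date",
    "ltd_records": "registration_date",
    "dispensings": "dispense_date",
    "procedures": "procedure_date",
    "reimbursements": "event_date",
}


@dataclasses.dataclass
class LoadReport:
    """What :func:`read_dataset` found while resolving and validating files."""

    rows_read: dict[str, int] = dataclasses.field(default_factory=dict)
    unresolved_drug_ids: int = 0
    unresolved_procedure_codes: int = 0
    warnings: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ClaimsDataset:
    persons: pd.DataFrame
    affiliations: pd.DataFrame
    stays: pd.DataFrame
    ltd_records: pd.DataFrame
    dispensings: pd.DataFrame
    procedures: pd.DataFrame
    reimbursements: pd.DataFrame
    observation_start: pd.Timestamp
    observation_end: pd.Timestamp  # inclusive last observed day

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in SCHEMAS}

    def events_for(self, person_ids) -> dict[str, pd.DataFrame]:
        """Event tables restricted to the given person ids (persons excluded)."""
        ids = pd.Index(person_ids)
        out = {}
        for name, col in EVENT_DATE_COL.items():
            tab = getattr(self, name)
            out[name] = tab[tab["person_id"].isin(ids)]
        return out


def _empty_table(name: str) -> pd.DataFrame:
    cols = SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
    for c in _DATE_COLS[name]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    if "person_id" in cols:
        df["person_id"] = pd.Series(dtype="int64")
    return df


def validate_dataset(ds: ClaimsDataset) -> None:
    """Check the dataset invariants; raise Schema/Referential errors.

    Checks: required columns, enumerated values, ICD-10 shape, referential
    integrity of person_id, event dates inside the observation window,
    death_date not earlier than any event, affiliation intervals ordered,
    non-overlapping and non-empty.
    """
    for name, cols in SCHEMAS.items():
        tab = getattr(ds, name)
        for c in cols:
            if c not in tab.columns:
                raise SchemaError(f"{name}: missing mandatory column {c!r}")

    p = ds.persons
    bad_sex = ~p["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError(f"persons.sex: invalid values {sorted(p.loc[bad_sex, 'sex'].unique())}")
    if p["person_id"].duplicated().any():
        raise SchemaError("persons.person_id: duplicate keys")

    st = ds.stays
    bad_pos = ~st["position"].isin(POSITIONS)
    if bad_pos.any():
        raise SchemaError(
            f"HospitalStay.position: invalid values {sorted(st.loc[bad_pos, 'position'].astype(str).unique())}"
        )
    for name, col in (("stays", "icd10_code"), ("ltd_records", "icd10_code")):
        codes = getattr(ds, name)[col].astype(str)
        if len(codes) and not codes.str.match(_ICD10_RE.pattern).all():
            bad = codes[~codes.str.match(_ICD10_RE.pattern)].unique()[:5]
            raise SchemaError(f"{name}.{col}: malformed ICD-10 codes {list(bad)}")

    known = pd.Index(p["person_id"])
    death = p.set_index("person_id")["death_date"]
    for name, datecol in EVENT_DATE_COL.items():
        tab = getattr(ds, name)
        if len(tab) == 0:
            continue
        unknown = ~tab["person_id"].isin(known)
        if unknown.any():
            rows = tab.index[unknown][:10].tolist()
            raise ReferentialError(f"{name}: unknown person_id at rows {rows}")
        dates = tab[datecol]
        if (dates < ds.observation_start).any() or (dates > ds.observation_end).any():
            raise SchemaError(f"{name}.{datecol}: dates outside observation window")
        d = tab["person_id"].map(death)
        if ((d.notna()) & (dates > d)).any():
            raise SchemaError(f"{name}: event after death_date")

    aff = ds.affiliations.sort_values(["person_id", "start_date"])
    if len(aff):
        if (aff["end_date"] <= aff["start_date"]).any():
            raise SchemaError("affiliations: empty or inverted interval")
        same = aff["person_id"].eq(aff["person_id"].shift())
        overlap = same & (aff["start_date"] < aff["end_date"].shift())
        if overlap.any():
            raise SchemaError("affiliations: overlapping intervals for a person")


def read_dataset(
    path: str | Path | Mapping[str, str | Path],
    codelists: CodeListConfig | None = None,
    observation_window: tuple | None = None,
    validate: bool = True,
) -> tuple[ClaimsDataset, LoadReport]:
    """Load a dataset from a directory (or explicit per-table paths).

    ``drug_class`` and procedure ``kind`` are resolved through *codelists*;
    codes absent from every list map to ``other`` and are counted in the
    returned :class:`LoadReport`.
    """
    codelists = codelists or CodeListConfig()
    report = LoadReport()

    if isinstance(path, (str, Path)):
        base = Path(path)
        paths = {name: base / fname for name, fname in TABLE_FILES.items()}
        meta_path = base / META_FILE
    else:
        paths = {name: Path(p) for name, p in path.items()}
        meta_path = None

    tables: dict[str, pd.DataFrame] = {}
    for name in SCHEMAS:
        fp = paths.get(name)
        if fp is None or not Path(fp).exists():
            tables[name] = _empty_table(name)
            report.warnings.append(f"{name}: file missing, using empty table")
            continue
        df = pd.read_csv(fp)
        for c in _FILE_REQUIRED[name]:
            if c not in df.columns:
                raise SchemaError(f"{name}: missing mandatory column {c!r} in {fp}")
        for c in _DATE_COLS[name]:
            if c in df.columns:
                df[c] = pd.to_datetime(df[c], format="ISO8601")
            else:
                df[c] = pd.NaT
        df["person_id"] = df["person_id"].astype("int64")
        tables[name] = df
        report.rows_read[name] = len(df)

    disp = tables["dispensings"]
    if len(disp):
        disp["drug_class"] = codelists.classify_drug_ids(disp["drug_id"].astype(str))
        n_other = int((disp["drug_class"] == "other").sum())
        report.unresolved_drug_ids = n_other
        if n_other:
            report.warnings.append(f"dispensings: {n_other} rows with drug_id absent from code lists → drug_class=other")
    else:
        disp["drug_class"] = pd.Series(dtype="object")

    proc = tables["procedures"]
    if len(proc):
        proc["kind"] = codelists.classify_procedure_codes(proc["procedure_code"].astype(str))
        n_other = int((proc["kind"] == "other").sum())
        report.unresolved_procedure_codes = n_other
        if n_other:
            report.warnings.append(f"procedures: {n_other} rows with code absent from code lists → kind=other")
    else:
        proc["kind"] = pd.Series(dtype="object")

    if observation_window is None and meta_path is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        observation_window = (meta["observation_start"], meta["observation_end"])
    if observation_window is None:
        dates = [tables[n][c].dropna() for n, cols in _DATE_COLS.items() for c in cols]
        dates = [d for d in dates if len(d)]
        if not dates:
            raise SchemaError("cannot infer observation window from empty dataset")
        observation_window = (min(d.min() for d in dates), max(d.max() for d in dates))
        report.warnings.append("observation window inferred from event dates")

    ds = ClaimsDataset(
        persons=tables["persons"],
        affiliations=tables["affiliations"],
        stays=tables["stays"],
        ltd_records=tables["ltd_records"],
        dispensings=tables["dispensings"],
        procedures=tables["procedures"],
        reimbursements=tables["reimbursements"],
        observation_start=pd.Timestamp(observation_window[0]),
        observation_end=pd.Timestamp(observation_window[1]),
    )
    if validate:
        validate_dataset(ds)
    return ds, report


def write_dataset(ds: ClaimsDataset, out_dir: str | Path) -> None:
    """Write all tables as CSV (ISO dates) plus ``meta.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, fname in TABLE_FILES.items():
        tab = getattr(ds, name).copy()
        for c in _DATE_COLS[name]:
            tab[c] = tab[c].dt.strftime("%Y-%m-%d")
        tab.to_csv(out / fname, index=False)
    meta = {
        "observation_start": ds.observation_start.strftime("%Y-%m-%d"),
        "observation_end": ds.observation_end.strftime("%Y-%m-%d"),
    }
    (out / META_FILE).write_text(json.dumps(meta, indent=2) + "\n")
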