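"""Cohort identification: the MYLORD algorithm and the PALMARO comparator.

MYLORD includes an adult (≥18 years at first qualifying evidence) when either

* **hosp_or_ltd_treated** — at least one hospital stay with a PD/RD/SAD
  diagnosis matching ``C90*`` *or* a long-term-disease registration for
  ``C90*``, **and** at least one MM treatment event (MM-specific drug,
  chemotherapy, or autologous stem-cell transplantation), all inside the
  identification period; or
* **oral_imid_monitored** — the same immunomodulatory drug (lenalidomide or
  thalidomide) dispensed on two distinct dates at most 90 days apart inside
  the identification period, with at least two protein-electrophoresis
  events (SPEP/UPEP, any mix) within 120 days of the first in-period
  dispensing of that drug, and no hospital stay anywhere in the database
  carrying one of the configured exclusion diagnoses (the non-myeloma
  indications of those drugs).

PALMARO includes adults (>18) with a ``C90*`` stay or LTD registration in
2014–2020, regardless of treatment; its two comparison variants extend the
identification period to 2006 or add the MYLORD treatment requirement.

Conventions (also surfaced as :class:`AlgorithmConfig` fields):
"within 90 days" is an inclusive difference between *distinct* dispensing
dates — a same-day double dispensing does not count; the monitoring window
is the closed interval ``[d, d+120]`` days; the exclusion-diagnosis lookup
spans the whole database history by default; treatment need not postdate
the stay/LTD.  A stay and an LTD registration tied on the same first date
are reported under the combined kind ``stay_and_ltd``.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .claims import ClaimsDataset
from .codes import CodeListConfig, icd10_mask

__all__ = [
    "AlgorithmConfig",
    "OralRuleResult",
    "mm_hospital_dates",
    "mm_treatment_dates",
    "oral_imid_rule",
    "identify_mylord",
    "identify_palmaro",
    "PALMARO_VARIANTS",
]

PALMARO_VARIANTS = ("base", "from_2006", "treated_only")

COHORT_COLUMNS = [
    "person_id",
    "criterion",
    "first_mm_information_date",
    "first_mm_information_kind",
    "first_stay_date",
    "first_ltd_date",
    "first_treatment_date",
    "oral_qualifying_date",
    "oral_drug",
]


class AlgorithmConfig(BaseModel):
    """Tunable clauses of the identification rules."""

    identification_start: datetime.date = datetime.date(2006, 1, 1)
    identification_end: datetime.date = datetime.date(2020, 12, 31)
    adult_age_min: int = 18
    age_strictly_greater: bool = False  # PALMARO is printed ">18", MYLORD "≥18"
    imid_repeat_window_days: int = 90
    monitoring_window_days: int = 120
    exclusion_icd10: Optional[list[str]] = None  # None → code-list default
    exclusion_whole_history: bool = True
    treated_only: bool = False
    alive_on: Optional[datetime.date] = None  # optional eligibility filter

    @model_validator(mode="after")
    def _check(self):
        if self.identification_start >= self.identification_end:
            raise ValueError("identification_start must precede identification_end")
        if self.imid_repeat_window_days <= 0 or self.monitoring_window_days <= 0:
            raise ValueError("windows must be positive")
        return self

    @classmethod
    def mylord(cls, **overrides) -> "AlgorithmConfig":
        return cls(**overrides)

    @classmethod
    def palmaro(cls, variant: str = "base", **overrides) -> "AlgorithmConfig":
        if variant not in PALMARO_VARIANTS:
            raise ValueError(f"unknown PALMARO variant {variant!r}; expected one of {PALMARO_VARIANTS}")
        kw = dict(
            identification_start=datetime.date(2014, 1, 1),
            age_strictly_greater=True,
            treated_only=False,
        )
        if variant == "from_2006":
            kw["identification_start"] = datetime.date(2006, 1, 1)
        if variant == "treated_only":
            kw["treated_only"] = True
        kw.update(overrides)
        return cls(**kw)

    def exclusion_patterns(self, codelists: CodeListConfig) -> list[str]:
        return self.exclusion_icd10 if self.exclusion_icd10 is not None else codelists.exclusion_icd10


def _window(config: AlgorithmConfig) -> tuple[pd.Timestamp, pd.Timestamp]:
    return pd.Timestamp(config.identification_start), pd.Timestamp(config.identification_end)


# --------------------------------------------------------------------------
# per-person primitives
# --------------------------------------------------------------------------

def mm_hospital_dates(
    stays: pd.DataFrame, codelists: CodeListConfig, config: AlgorithmConfig
) -> list[pd.Timestamp]:
    """Ascending admission dates of one person's stays with any PD/RD/SAD
    diagnosis matching the MM code patterns, inside the identification period."""
    if len(stays) == 0:
        return []
    lo, hi = _window(config)
    m = icd10_mask(stays["icd10_code"], codelists.mm_icd10)
    m &= stays["admission_date"].between(lo, hi).to_numpy()
    return sorted(stays.loc[m, "admission_date"].unique())


def mm_treatment_dates(
    dispensings: pd.DataFrame,
    procedures: pd.DataFrame,
    codelists: CodeListConfig,
    config: AlgorithmConfig,
) -> list[pd.Timestamp]:
    """Ascending dates of MM-specific drug, chemotherapy or ASCT events in-window."""
    lo, hi = _window(config)
    dates: list = []
    if len(dispensings):
        m = dispensings["drug_class"].isin(["mm_specific", "chemotherapy"]).to_numpy()
        m &= dispensings["dispense_date"].between(lo, hi).to_numpy()
        dates.extend(dispensings.loc[m, "dispense_date"])
    if len(procedures):
        m = (procedures["kind"] == "ASCT").to_numpy()
        m &= procedures["procedure_date"].between(lo, hi).to_numpy()
        dates.extend(procedures.loc[m, "procedure_date"])
    return sorted(pd.unique(pd.Series(dates))) if dates else []


@dataclasses.dataclass
class OralRuleResult:
    qualifies: bool
    qualifying_date: Optional[pd.Timestamp] = None
    drug: Optional[str] = None
    details: dict = dataclasses.field(default_factory=dict)


def oral_imid_rule(
    dispensings: pd.DataFrame,
    procedures: pd.DataFrame,
    stays: pd.DataFrame,
    config: AlgorithmConfig,
    codelists: CodeListConfig,
) -> OralRuleResult:
    """Evaluate the oral-IMiD inclusion arm for one person.

    Qualifies iff (a) the same drug (lenalidomide or thalidomide) was
    dispensed on two distinct dates ≤ ``imid_repeat_window_days`` apart,
    both inside the identification period; (b) counting from the first
    in-period dispensing date ``d`` of that drug, at least two SPEP/UPEP
    events fall within ``[d, d + monitoring_window_days]``; and (c) no
    hospital stay carries an exclusion diagnosis.  The qualifying date is
    ``d`` (earliest across the two drugs when both qualify).
    """
    lo, hi = _window(config)

    # clause (c): exclusion diagnoses
    if len(stays):
        s = stays
        if not config.exclusion_whole_history:
            s = s[s["admission_date"].between(lo, hi)]
        if len(s) and icd10_mask(s["icd10_code"], config.exclusion_patterns(codelists)).any():
            return OralRuleResult(False, details={"excluded_by_diagnosis": True})

    proc_dates = (
        procedures.loc[procedures["kind"].isin(["SPEP", "UPEP"]), "procedure_date"]
        if len(procedures)
        else pd.Series([], dtype="datetime64[ns]")
    )

    best: Optional[OralRuleResult] = None
    for drug in ("lenalidomide", "thalidomide"):
        if len(dispensings) == 0:
            break
        m = (dispensings["drug_class"] == drug).to_numpy()
        m &= dispensings["dispense_date"].between(lo, hi).to_numpy()
        dates = np.sort(dispensings.loc[m, "dispense_date"].unique())
        if len(dates) < 2:
            continue
        diffs = np.diff(dates).astype("timedelta64[D]").astype(int)
        if diffs.min() > config.imid_repeat_window_days:
            continue  # clause (a) fails: no two distinct dates close enough
        d = pd.Timestamp(dates[0])
        w_end = d + pd.Timedelta(days=config.monitoring_window_days)
        n_monitoring = int(proc_dates.between(d, w_end).sum())
        if n_monitoring < 2:
            continue  # clause (b) fails
        res = OralRuleResult(
            True,
            qualifying_date=d,
            drug=drug,
            details={
                "dispensing_dates": [pd.Timestamp(x) for x in dates[:2]],
                "monitoring_events_in_window": n_monitoring,
            },
        )
        if best is None or res.qualifying_date < best.qualifying_date:
            best = res
    return best if best is not None else OralRuleResult(False)


# --------------------------------------------------------------------------
# cohort-level identification (vectorized with a small loop for the oral arm)
# --------------------------------------------------------------------------

def _first_per_person(df: pd.DataFrame, mask: np.ndarray, date_col: str) -> pd.Series:
    if len(df) == 0 or not mask.any():
        return pd.Series(dtype="datetime64[ns]")
    return df.loc[mask].groupby("person_id")[date_col].min()

def _first_mm_stay_ltd_treatment(
    ds: ClaimsDataset, config: AlgorithmConfig, codelists: CodeListConfig
) -> tuple[pd.Series, pd.Series, pd.Series]:
    lo, hi = _window(config)
    st = ds.stays
    m = icd10_mask(st["icd10_code"], codelists.mm_icd10) if len(st) else np.zeros(0, bool)
    if len(st):
        m &= st["admission_date"].between(lo, hi).to_numpy()
    first_stay = _first_per_person(st, m, "admission_date")

    ltd = ds.ltd_records
    m = icd10_mask(ltd["icd10_code"], codelists.mm_icd10) if len(ltd) else np.zeros(0, bool)
    if len(ltd):
        m &= ltd["registration_date"].between(lo, hi).to_numpy()
    first_ltd = _first_per_person(ltd, m, "registration_date")

    disp = ds.dispensings
    m = disp["drug_class"].isin(["mm_specific", "chemotherapy"]).to_numpy() if len(disp) else np.zeros(0, bool)
    if len(disp):
        m &= disp["dispense_date"].between(lo, hi).to_numpy()
    first_drug = _first_per_person(disp, m, "dispense_date")
    proc = ds.procedures
    m = (proc["kind"] == "ASCT").to_numpy() if len(proc) else np.zeros(0, bool)
    if len(proc):
        m &= proc["procedure_date"].between(lo, hi).to_numpy()
    first_asct = _first_per_person(proc, m, "procedure_date")
    parts = [s for s in (first_drug, first_asct) if len(s)]
    first_treat = (
        pd.concat(parts).groupby(level=0).min() if parts else pd.Series(dtype="datetime64[ns]")
    )
    return first_stay, first_ltd, first_treat


def _oral_arm(ds: ClaimsDataset, config: AlgorithmConfig, codelists: CodeListConfig) -> pd.DataFrame:
    """Evaluate the oral-IMiD rule for every person with ≥2 in-window IMiD
    dispensings; returns person_id, oral_qualifying_date, oral_drug."""
    lo, hi = _window(config)
    disp = ds.dispensings
    if len(disp) == 0:
        return pd.DataFrame(columns=["person_id", "oral_qualifying_date", "oral_drug"])
    m = disp["drug_class"].isin(["lenalidomide", "thalidomide"]).to_numpy()
    m &= disp["dispense_date"].between(lo, hi).to_numpy()
    imid = disp.loc[m]
    counts = imid.drop_duplicates(["person_id", "drug_class", "dispense_date"]).groupby(
        ["person_id", "drug_class"]
    ).size()
    candidates = counts[counts >= 2].index.get_level_values("person_id").unique()
    if len(candidates) == 0:
        return pd.DataFrame(columns=["person_id", "oral_qualifying_date", "oral_drug"])

    cand = pd.Index(candidates)
    disp_by = {pid: g for pid, g in disp[disp["person_id"].isin(cand)].groupby("person_id")}
    proc = ds.procedures
    proc_by = {pid: g for pid, g in proc[proc["person_id"].isin(cand)].groupby("person_id")} if len(proc) else {}
    stays = ds.stays
    stays_by = {pid: g for pid, g in stays[stays["person_id"].isin(cand)].groupby("person_id")} if len(stays) else {}
    empty_proc = proc.iloc[0:0] if len(proc) else pd.DataFrame(columns=["person_id", "procedure_date", "kind"])
    empty_stays = stays.iloc[0:0] if len(stays) else pd.DataFrame(columns=["person_id", "admission_date", "icd10_code"])

    rows = []
    for pid in cand:
        res = oral_imid_rule(
            disp_by[pid],
            proc_by.get(pid, empty_proc),
            stays_by.get(pid, empty_stays),
            config,
            codelists,
        )
        if res.qualifies:
            rows.append((pid, res.qualifying_date, res.drug))
    return pd.DataFrame(rows, columns=["person_id", "oral_qualifying_date", "oral_drug"])


def _age_ok(persons: pd.DataFrame, person_ids: pd.Index, info_dates: pd.Series, config: AlgorithmConfig) -> pd.Series:
    """Adult-age filter: age (analysis-year minus birth_year) at first
    qualifying evidence, ≥ or > the threshold per configuration."""
    by = persons.set_index("person_id")["birth_year"]
    ages = info_dates.dt.year - by.reindex(person_ids).to_numpy()
    if config.age_strictly_greater:
        return ages > config.adult_age_min
    return ages >= config.adult_age_min


def _alive_ok(persons: pd.DataFrame, person_ids: pd.Index, config: AlgorithmConfig) -> pd.Series:
    if config.alive_on is None:
        return pd.Series(True, index=person_ids)
    death = persons.set_index("person_id")["death_date"].reindex(person_ids)
    return death.isna() | (death >= pd.Timestamp(config.alive_on))


def _kind_of_first(row: pd.Series) -> str:
    first = row["first_mm_information_date"]
    stay_hit = pd.notna(row["first_stay_date"]) and row["first_stay_date"] == first
    ltd_hit = pd.notna(row["first_ltd_date"]) and row["first_ltd_date"] == first
    if stay_hit and ltd_hit:
        return "stay_and_ltd"
    if stay_hit:
        return "hospital_stay"
    if ltd_hit:
        return "ltd"
    if pd.notna(row["first_treatment_date"]) and row["first_treatment_date"] == first:
        return "treatment"
    return "oral_rule"


def identify_mylord(
    ds: ClaimsDataset,
    config: AlgorithmConfig | None = None,
    codelists: CodeListConfig | None = None,
) -> pd.DataFrame:
    """Run the MYLORD algorithm; one row per included person.

    ``first_mm_information_date`` is the earliest date among the satisfied
    clauses (C90* stay, C90* LTD, treatment, oral qualifying date);
    ``criterion`` is ``hosp_or_ltd_treated`` when the stay/LTD+treatment arm
    is satisfied (even if the oral arm also is), else ``oral_imid_monitored``.
    """
    config = config or AlgorithmConfig.mylord()
    codelists = codelists or CodeListConfig()

    first_stay, first_ltd, first_treat = _first_mm_stay_ltd_treatment(ds, config, codelists)
    arm1_ids = first_stay.index.union(first_ltd.index).intersection(first_treat.index)

    oral = _oral_arm(ds, config, codelists).set_index("person_id")
    all_ids = arm1_ids.union(oral.index)
    if len(all_ids) == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    out = pd.DataFrame(index=all_ids)
    out.index.name = "person_id"
    in_arm1 = out.index.isin(arm1_ids)
    # clause dates only count toward first information when their arm is satisfied
    out["first_stay_date"] = first_stay.reindex(out.index).where(in_arm1)
    out["first_ltd_date"] = first_ltd.reindex(out.index).where(in_arm1)
    out["first_treatment_date"] = first_treat.reindex(out.index).where(in_arm1)
    out["oral_qualifying_date"] = oral["oral_qualifying_date"].reindex(out.index)
    out["oral_drug"] = oral["oral_drug"].reindex(out.index)
    for col in ("first_stay_date", "first_ltd_date", "first_treatment_date", "oral_qualifying_date"):
        out[col] = pd.to_datetime(out[col])
    out["first_mm_information_date"] = out[
        ["first_stay_date", "first_ltd_date", "first_treatment_date", "oral_qualifying_date"]
    ].min(axis=1)
    out["criterion"] = np.where(in_arm1, "hosp_or_ltd_treated", "oral_imid_monitored")
    out["first_mm_information_kind"] = out.apply(_kind_of_first, axis=1)

    keep = _age_ok(ds.persons, out.index, out["first_mm_information_date"], config)
    keep &= _alive_ok(ds.persons, out.index, config).to_numpy()
    out = out.loc[np.asarray(keep)]
    return out.reset_index()[COHORT_COLUMNS].sort_values("person_id").reset_index(drop=True)


def identify_palmaro(
    ds: ClaimsDataset,
    variant: str = "base",
    config: AlgorithmConfig | None = None,
    codelists: CodeListConfig | None = None,
) -> pd.DataFrame:
    """Run the PALMARO algorithm (``base``, ``from_2006`` or ``treated_only``).

    Inclusion rests on a C90* stay or LTD registration in the identification
    period; ``treated_only`` additionally requires an MM treatment date
    (same treatment list as MYLORD).  First MM information is the earlier of
    the stay and LTD dates.
    """
    if variant not in PALMARO_VARIANTS:
        raise ValueError(f"unknown PALMARO variant {variant!r}; expected one of {PALMARO_VARIANTS}")
    config = config or AlgorithmConfig.palmaro(variant)
    codelists = codelists or CodeListConfig()

    first_stay, first_ltd, first_treat = _first_mm_stay_ltd_treatment(ds, config, codelists)
    ids = first_stay.index.union(first_ltd.index)
    if config.treated_only or variant == "treated_only":
        ids = ids.intersection(first_treat.index)
    if len(ids) == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    out = pd.DataFrame(index=ids)
    out.index.name = "person_id"
    out["first_stay_date"] = first_stay.reindex(out.index)
    out["first_ltd_date"] = first_ltd.reindex(out.index)
    out["first_treatment_date"] = first_treat.reindex(out.index)
    out["oral_qualifying_date"] = pd.NaT
    out["oral_drug"] = None
    out["first_mm_information_date"] = out[["first_stay_date", "first_ltd_date"]].min(axis=1)
    out["criterion"] = "hosp_or_ltd" if not (config.treated_only or variant == "treated_only") else "hosp_or_ltd_treated"
    out["first_mm_information_kind"] = out.apply(_kind_of_first_palmaro, axis=1)

    keep = _age_ok(ds.persons, out.index, out["first_mm_information_date"], config)
    keep &= _alive_ok(ds.persons, out.index, config).to_numpy()
    out = out.loc[np.asarray(keep)]
    return out.reset_index()[COHORT_COLUMNS].sort_values("person_id").reset_index(drop=True)


def _kind_of_first_palmaro(row: pd.Series) -> str:
    first = row["first_mm_information_date"]
    stay_hit = pd.notna(row["first_stay_date"]) and row["first_stay_date"] == first
    ltd_hit = pd.notna(row["first_ltd_date"]) and row["first_ltd_date"] == first
    if stay_hit and ltd_hit:
        return "stay_and_ltd"
    return "hospital_stay" if stay_hit else "ltd"
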