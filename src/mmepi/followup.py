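"""Index dates, incident/prevalent classification, and follow-up censoring.

Study conventions: the study period runs 2014-01-01 to 2020-12-31 with
history available from 2006.  The index date is the first MM-treatment
date inside the study period, or 2014-01-01 for patients already treated
before (for the oral arm the qualifying first dispensing counts as
treatment).  A patient is *incident* in the year of their first in-study
MM information if no MM information of any kind falls in the 730 days
before it (the incident-user washout); otherwise they are prevalent at
entry.  Follow-up runs from the first in-study MM information date
(2014-01-01 for prevalent patients) until death, the study end, or the
last reimbursed event followed by more than 730 reimbursement-free days,
whichever comes first.  "Two years" is a fixed 730 days throughout, with
no leap-year adjustment; both windows are configuration fields.
"""

from __future__ import annotations

import datetime
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .claims import ClaimsDataset
from .codes import CodeListConfig, icd10_mask
from .cohort import AlgorithmConfig

__all__ = [
    "FollowupConfig",
    "mm_information_dates",
    "assign_index_date",
    "classify_incident",
    "compute_followup_end",
    "build_followup",
]

END_REASONS = ("death", "study_end", "reimbursement_gap")


class FollowupConfig(BaseModel):
    study_start: datetime.date = datetime.date(2014, 1, 1)
    study_end: datetime.date = datetime.date(2020, 12, 31)
    washout_days: int = 730
    gap_days: int = 730
    history_start: datetime.date = datetime.date(2006, 1, 1)


def assign_index_date(
    treatment_dates: Iterable[pd.Timestamp],
    config: FollowupConfig,
    fallback: Optional[pd.Timestamp] = None,
) -> pd.Timestamp:
    """First in-study treatment date, or the study start when treatment
    predates it.  *fallback* (first in-study MM information) covers cohorts
    whose inclusion does not require treatment; a treatment-requiring member
    without any treatment date is an internal consistency error."""
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    dates = sorted(pd.Timestamp(d) for d in treatment_dates)
    if not dates:
        if fallback is None:
            raise ValueError("cohort member with no treatment date and no fallback information date")
        return max(pd.Timestamp(fallback), start)
    if dates[0] < start:
        return start
    in_study = [d for d in dates if start <= d <= end]
    return in_study[0] if in_study else start


def classify_incident(
    info_dates: Iterable[pd.Timestamp], config: FollowupConfig
) -> Optional[int]:
    """Incident year, or None for a prevalent-at-entry member.

    *info_dates* is every MM information date of the person over the full
    history (C90* stays, C90* LTD registrations, MM treatments, the oral
    qualifying date).  The member is incident in the year of the first
    in-study date iff no information falls within the preceding
    ``washout_days``, and that lookback is fully covered by the available
    history (an incomplete lookback cannot establish incidence).
    """
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    dates = sorted(pd.Timestamp(d) for d in info_dates)
    in_study = [d for d in dates if start <= d <= end]
    if not in_study:
        return None
    f = in_study[0]
    w_lo = f - pd.Timedelta(days=config.washout_days)
    if w_lo < pd.Timestamp(config.history_start):
        return None  # insufficient lookback
    if any(w_lo <= d < f for d in dates):
        return None
    return int(f.year)


def compute_followup_end(
    followup_start: pd.Timestamp,
    reimbursement_dates: Iterable[pd.Timestamp],
    death_date: Optional[pd.Timestamp],
    config: FollowupConfig,
) -> tuple[pd.Timestamp, str]:
    """Follow-up end and its reason (death / study_end / reimbursement_gap).

    Gap censoring fires at the last reimbursed event (the follow-up start
    acting as the initial anchor) followed by more than ``gap_days`` with no
    reimbursement while the person is still under observation; ties are
    resolved death > study_end > gap.
    """
    start = pd.Timestamp(followup_start)
    study_end = pd.Timestamp(config.study_end)
    death = pd.Timestamp(death_date) if death_date is not None and pd.notna(death_date) else None
    other_end = min(study_end, death) if death is not None else study_end

    dates = sorted({pd.Timestamp(d) for d in reimbursement_dates if pd.Timestamp(d) >= start})
    anchors = [start] + dates
    gap_date = None
    for a, b in zip(anchors, anchors[1:]):
        if a >= other_end:
            break
        if (b - a).days > config.gap_days:
            gap_date = a
            break
    if gap_date is None:
        last = anchors[-1]
        trailing_limit = death if death is not None else study_end
        if last < other_end and (trailing_limit - last).days > config.gap_days:
            gap_date = last

    candidates: list[tuple[pd.Timestamp, str]] = []
    if death is not None:
        candidates.append((death, "death"))
    candidates.append((study_end, "study_end"))
    if gap_date is not None:
        candidates.append((gap_date, "reimbursement_gap"))
    best_date = min(d for d, _ in candidates)
    priority = {"death": 0, "study_end": 1, "reimbursement_gap": 2}
    reason = min((r for d, r in candidates if d == best_date), key=priority.get)
    return max(best_date, start), reason


def mm_information_dates(
    ds: ClaimsDataset,
    person_ids: Iterable[int],
    codelists: CodeListConfig,
    algo_config: AlgorithmConfig,
    include_treatment: bool = True,
) -> dict[int, list[pd.Timestamp]]:
    """Per-person MM information dates over the full history (no window
    clipping): C90* stay admissions, C90* LTD registrations and, when
    *include_treatment*, MM-specific/chemotherapy dispensings and ASCT."""
    ids = pd.Index(pd.unique(pd.Series(list(person_ids))))
    out: dict[int, list] = {int(p): [] for p in ids}

    st = ds.stays
    if len(st):
        m = st["person_id"].isin(ids).to_numpy() & icd10_mask(st["icd10_code"], codelists.mm_icd10)
        for pid, d in zip(st.loc[m, "person_id"], st.loc[m, "admission_date"]):
            out[int(pid)].append(d)
    lt = ds.ltd_records
    if len(lt):
        m = lt["person_id"].isin(ids).to_numpy() & icd10_mask(lt["icd10_code"], codelists.mm_icd10)
        for pid, d in zip(lt.loc[m, "person_id"], lt.loc[m, "registration_date"]):
            out[int(pid)].append(d)
    if include_treatment:
        dp = ds.dispensings
        if len(dp):
            m = dp["person_id"].isin(ids).to_numpy() & dp["drug_class"].isin(
                ["mm_specific", "chemotherapy"]
            ).to_numpy()
            for pid, d in zip(dp.loc[m, "person_id"], dp.loc[m, "dispense_date"]):
                out[int(pid)].append(d)
        pr = ds.procedures
        if len(pr):
            m = pr["person_id"].isin(ids).to_numpy() & (pr["kind"] == "ASCT").to_numpy()
            for pid, d in zip(pr.loc[m, "person_id"], pr.loc[m, "procedure_date"]):
                out[int(pid)].append(d)
    return out


def treatment_dates_by_person(
    ds: ClaimsDataset, person_ids: Iterable[int], codelists: CodeListConfig
) -> dict[int, list[pd.Timestamp]]:
    """MM treatment dates only (MM-specific/chemotherapy dispensings, ASCT),
    over the full history."""
    ids = pd.Index(pd.unique(pd.Series(list(person_ids))))
    out: dict[int, list] = {int(p): [] for p in ids}
    dp = ds.dispensings
    if len(dp):
        m = dp["person_id"].isin(ids).to_numpy() & dp["drug_class"].isin(
            ["mm_specific", "chemotherapy"]
        ).to_numpy()
        for pid, d in zip(dp.loc[m, "person_id"], dp.loc[m, "dispense_date"]):
            out[int(pid)].append(d)
    pr = ds.procedures
    if len(pr):
        m = pr["person_id"].isin(ids).to_numpy() & (pr["kind"] == "ASCT").to_numpy()
        for pid, d in zip(pr.loc[m, "person_id"], pr.loc[m, "procedure_date"]):
            out[int(pid)].append(d)
    return out


def build_followup(
    ds: ClaimsDataset,
    cohort: pd.DataFrame,
    codelists: CodeListConfig | None = None,
    algo_config: AlgorithmConfig | None = None,
    config: FollowupConfig | None = None,
    include_treatment_in_information: bool = True,
) -> pd.DataFrame:
    """Follow-up table for an identified cohort.

    Columns: person_id, index_date, entry_status, incident_year,
    followup_start, followup_end, end_reason.
    """
    codelists = codelists or CodeListConfig()
    algo_config = algo_config or AlgorithmConfig.mylord()
    config = config or FollowupConfig()
    start = pd.Timestamp(config.study_start)

    if len(cohort) == 0:
        return pd.DataFrame(
            columns=[
                "person_id", "index_date", "entry_status", "incident_year",
                "followup_start", "followup_end", "end_reason",
            ]
        )

    ids = cohort["person_id"].tolist()
    info = mm_information_dates(ds, ids, codelists, algo_config, include_treatment_in_information)
    oral_dates = cohort.set_index("person_id")["oral_qualifying_date"]
    for pid, d in oral_dates.items():
        if pd.notna(d):
            info[int(pid)].append(pd.Timestamp(d))

    # treatment dates for index assignment (oral qualifying date included)
    treat = treatment_dates_by_person(ds, ids, codelists)
    death = ds.persons.set_index("person_id")["death_date"]

    # reimbursed events per person (stays, dispensings, procedures, other
    # reimbursements) gathered once, vectorized
    ev = []
    for tab, col in (
        (ds.stays, "admission_date"),
        (ds.dispensings, "dispense_date"),
        (ds.procedures, "procedure_date"),
        (ds.reimbursements, "event_date"),
    ):
        if len(tab):
            sub = tab[tab["person_id"].isin(ids)]
            ev.append(sub[["person_id", col]].rename(columns={col: "date"}))
    events = pd.concat(ev, ignore_index=True) if ev else pd.DataFrame(columns=["person_id", "date"])
    events_by: dict[int, np.ndarray] = {
        int(pid): g["date"].to_numpy() for pid, g in events.groupby("person_id")
    }

    rows = []
    for pid in ids:
        pid = int(pid)
        dates = sorted(info[pid])
        incident_year = classify_incident(dates, config)
        in_study = [d for d in dates if start <= d <= pd.Timestamp(config.study_end)]
        f = in_study[0] if in_study else None
        fu_start = f if incident_year is not None else start
        if fu_start is None:
            fu_start = start
        tdates = set(treat.get(pid, []))
        od = oral_dates.get(pid)
        if pd.notna(od):
            tdates.add(pd.Timestamp(od))
        index_date = assign_index_date(sorted(tdates), config, fallback=f)
        fu_end, reason = compute_followup_end(fu_start, events_by.get(pid, ()), death.get(pid), config)
        entry = f"incident_in_year_{incident_year}" if incident_year is not None else "prevalent_at_2014"
        rows.append((pid, index_date, entry, incident_year, fu_start, fu_end, reason))

    out = pd.DataFrame(
        rows,
        columns=[
            "person_id", "index_date", "entry_status", "incident_year",
            "followup_start", "followup_end", "end_reason",
        ],
    )
    out["incident_year"] = out["incident_year"].astype("Int64")
    return out
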