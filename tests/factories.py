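"""Small hand-built datasets for unit tests."""

from __future__ import annotations

import pandas as pd

from mmepi.claims import ClaimsDataset
from mmepi.codes import CodeListConfig


def make_dataset(
    persons,
    stays=(),
    ltd=(),
    disp=(),
    proc=(),
    reimb=(),
    affiliations=None,
    window=("2006-01-01", "2020-12-31"),
    codelists: CodeListConfig | None = None,
) -> ClaimsDataset:
    """Assemble a ClaimsDataset from terse tuples.

    persons: (person_id, sex, birth_year[, death_date])
    stays:   (person_id, date, icd10, position[, stay_id])
    ltd:     (person_id, date, icd10)
    disp:    (person_id, date, drug_id)
    proc:    (person_id, date, procedure_code)
    reimb:   (person_id, date)
    affiliations default to full-window coverage for every person.
    """
    cl = codelists or CodeListConfig()
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])

    prows = []
    for p in persons:
        pid, sex, by = p[0], p[1], p[2]
        death = pd.Timestamp(p[3]) if len(p) > 3 and p[3] is not None else pd.NaT
        prows.append((pid, sex, by, death))
    persons_df = pd.DataFrame(prows, columns=["person_id", "sex", "birth_year", "death_date"])
    persons_df["death_date"] = pd.to_datetime(persons_df["death_date"])

    if affiliations is None:
        aff = pd.DataFrame(
            {
                "person_id": persons_df["person_id"],
                "start_date": start,
                "end_date": end + pd.Timedelta(days=1),
            }
        )
    else:
        aff = pd.DataFrame(affiliations, columns=["person_id", "start_date", "end_date"])
        aff["start_date"] = pd.to_datetime(aff["start_date"])
        aff["end_date"] = pd.to_datetime(aff["end_date"])

    srows = []
    for i, s in enumerate(stays):
        sid = s[4] if len(s) > 4 else i + 1
        srows.append((s[0], sid, pd.Timestamp(s[1]), s[2], s[3]))
    stays_df = pd.DataFrame(srows, columns=["person_id", "stay_id", "admission_date", "icd10_code", "position"])
    stays_df["admission_date"] = pd.to_datetime(stays_df["admission_date"])

    ltd_df = pd.DataFrame(
        [(r[0], pd.Timestamp(r[1]), r[2]) for r in ltd],
        columns=["person_id", "registration_date", "icd10_code"],
    )
    ltd_df["registration_date"] = pd.to_datetime(ltd_df["registration_date"])

    disp_df = pd.DataFrame(
        [(r[0], pd.Timestamp(r[1]), r[2]) for r in disp],
        columns=["person_id", "dispense_date", "drug_id"],
    )
    disp_df["dispense_date"] = pd.to_datetime(disp_df["dispense_date"])
    disp_df["drug_class"] = (
        cl.classify_drug_ids(disp_df["drug_id"].astype(str)) if len(disp_df) else pd.Series(dtype=object)
    )

    proc_df = pd.DataFrame(
        [(r[0], pd.Timestamp(r[1]), r[2]) for r in proc],
        columns=["person_id", "procedure_date", "procedure_code"],
    )
    proc_df["procedure_date"] = pd.to_datetime(proc_df["procedure_date"])
    proc_df["kind"] = (
        cl.classify_procedure_codes(proc_df["procedure_code"].astype(str)) if len(proc_df) else pd.Series(dtype=object)
    )

    reimb_df = pd.DataFrame([(r[0], pd.Timestamp(r[1])) for r in reimb], columns=["person_id", "event_date"])
    reimb_df["event_date"] = pd.to_datetime(reimb_df["event_date"])

    for df in (persons_df, stays_df, ltd_df, disp_df, proc_df, reimb_df, aff):
        df["person_id"] = df["person_id"].astype("int64")

    return ClaimsDataset(
        persons=persons_df,
        affiliations=aff,
        stays=stays_df,
        ltd_records=ltd_df,
        dispensings=disp_df,
        procedures=proc_df,
        reimbursements=reimb_df,
        observation_start=start,
        observation_end=end,
    )


# frequently used codes (from the default example lists)
CL = CodeListConfig()
MM_DRUG = CL.mm_specific_drugs[0]
CHEMO = CL.chemotherapy_drugs[0]
LEN = CL.lenalidomide_drugs[0]
THAL = CL.thalidomide_drugs[0]
SPEP = CL.spep_procedures[0]
UPEP = CL.upep_procedures[0]
ASCT = CL.asct_procedures[0]
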