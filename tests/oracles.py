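"""Independent brute-force oracles used by the test suite.

Everything here is written as plain, naive Python loops directly from the
statement of each rule, deliberately avoiding the vectorized code paths in
``mmepi`` so that agreement between the two is meaningful evidence.
"""

from __future__ import annotations

import math

import pandas as pd

from mmepi.claims import ClaimsDataset
from mmepi.codes import CodeListConfig, match_icd10
from mmepi.cohort import AlgorithmConfig


def person_events(ds: ClaimsDataset, pid: int) -> dict:
    """Plain per-person event lists extracted row by row."""
    out = {"stays": [], "ltd": [], "disp": [], "proc": []}
    for _, r in ds.stays[ds.stays["person_id"] == pid].iterrows():
        out["stays"].append((r["admission_date"], r["icd10_code"], r["position"]))
    for _, r in ds.ltd_records[ds.ltd_records["person_id"] == pid].iterrows():
        out["ltd"].append((r["registration_date"], r["icd10_code"]))
    for _, r in ds.dispensings[ds.dispensings["person_id"] == pid].iterrows():
        out["disp"].append((r["dispense_date"], r["drug_class"]))
    for _, r in ds.procedures[ds.procedures["person_id"] == pid].iterrows():
        out["proc"].append((r["procedure_date"], r["kind"]))
    return out


def all_person_events(ds: ClaimsDataset) -> dict[int, dict]:
    """Same as :func:`person_events` for every person with any event."""
    out: dict[int, dict] = {}

    def rec(pid):
        return out.setdefault(int(pid), {"stays": [], "ltd": [], "disp": [], "proc": []})

    for _, r in ds.stays.iterrows():
        rec(r["person_id"])["stays"].append((r["admission_date"], r["icd10_code"], r["position"]))
    for _, r in ds.ltd_records.iterrows():
        rec(r["person_id"])["ltd"].append((r["registration_date"], r["icd10_code"]))
    for _, r in ds.dispensings.iterrows():
        rec(r["person_id"])["disp"].append((r["dispense_date"], r["drug_class"]))
    for _, r in ds.procedures.iterrows():
        rec(r["person_id"])["proc"].append((r["procedure_date"], r["kind"]))
    return out


def _is_mm_code(code, cl: CodeListConfig) -> bool:
    return any(match_icd10(code, p) for p in cl.mm_icd10)


def _in_window(d, cfg: AlgorithmConfig) -> bool:
    return pd.Timestamp(cfg.identification_start) <= d <= pd.Timestamp(cfg.identification_end)


def brute_oral_rule(ev: dict, cfg: AlgorithmConfig, cl: CodeListConfig):
    """(qualifies, qualifying date) for the oral-IMiD arm, by exhaustive
    pairwise search over dispensing dates."""
    for day, code, _pos in ev["stays"]:
        if any(match_icd10(code, p) for p in cl.exclusion_icd10):
            return False, None
    best = None
    for drug in ("lenalidomide", "thalidomide"):
        dates = sorted({d for d, c in ev["disp"] if c == drug and _in_window(d, cfg)})
        ok_pair = False
        for i in range(len(dates)):
            for j in range(i + 1, len(dates)):
                if dates[i] != dates[j] and abs((dates[j] - dates[i]).days) <= cfg.imid_repeat_window_days:
                    ok_pair = True
        if not ok_pair:
            continue
        d0 = dates[0]
        n_mon = 0
        for d, kind in ev["proc"]:
            if kind in ("SPEP", "UPEP") and d0 <= d <= d0 + pd.Timedelta(days=cfg.monitoring_window_days):
                n_mon += 1
        if n_mon >= 2 and (best is None or d0 < best):
            best = d0
    return (best is not None), best


def brute_mylord(ev: dict, birth_year: int, cfg: AlgorithmConfig, cl: CodeListConfig):
    """(included, first MM information date) per the dual-arm rule."""
    stay_dates = sorted(d for d, c, _p in ev["stays"] if _is_mm_code(c, cl) and _in_window(d, cfg))
    ltd_dates = sorted(d for d, c in ev["ltd"] if _is_mm_code(c, cl) and _in_window(d, cfg))
    treat_dates = sorted(
        [d for d, c in ev["disp"] if c in ("mm_specific", "chemotherapy") and _in_window(d, cfg)]
        + [d for d, k in ev["proc"] if k == "ASCT" and _in_window(d, cfg)]
    )
    firsts = []
    if (stay_dates or ltd_dates) and treat_dates:
        for lst in (stay_dates, ltd_dates, treat_dates):
            if lst:
                firsts.append(lst[0])
    oral_ok, oral_d = brute_oral_rule(ev, cfg, cl)
    if oral_ok:
        firsts.append(oral_d)
    if not firsts:
        return False, None
    first = min(firsts)
    age = first.year - birth_year
    if age < cfg.adult_age_min:
        return False, None
    return True, first


def brute_palmaro(ev: dict, birth_year: int, cfg: AlgorithmConfig, cl: CodeListConfig, treated: bool):
    stay_dates = sorted(d for d, c, _p in ev["stays"] if _is_mm_code(c, cl) and _in_window(d, cfg))
    ltd_dates = sorted(d for d, c in ev["ltd"] if _is_mm_code(c, cl) and _in_window(d, cfg))
    if not stay_dates and not ltd_dates:
        return False, None
    if treated:
        treat = [d for d, c in ev["disp"] if c in ("mm_specific", "chemotherapy") and _in_window(d, cfg)]
        treat += [d for d, k in ev["proc"] if k == "ASCT" and _in_window(d, cfg)]
        if not treat:
            return False, None
    first = min((stay_dates or ltd_dates[:1]) + (ltd_dates or stay_dates[:1]))
    age = first.year - birth_year
    if not (age > cfg.adult_age_min):
        return False, None
    return True, first


def brute_incident_year(info_dates, study_start, study_end, washout_days, history_start):
    """Washout scan over the full event history."""
    dates = sorted(pd.Timestamp(d) for d in info_dates)
    first = None
    for d in dates:
        if pd.Timestamp(study_start) <= d <= pd.Timestamp(study_end):
            first = d
            break
    if first is None:
        return None
    lo = first - pd.Timedelta(days=washout_days)
    if lo < pd.Timestamp(history_start):
        return None
    for d in dates:
        if lo <= d < first:
            return None
    return first.year


def brute_asr(counts, populations, weights, scale=100_000.0) -> float:
    """Term-by-term direct standardization with compensated summation."""
    terms = []
    for x, n, w in zip(counts, populations, weights):
        if n == 0:
            if x:
                raise ValueError("events with zero population")
            continue
        terms.append(w * (x / n) * scale)
    return math.fsum(terms)
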