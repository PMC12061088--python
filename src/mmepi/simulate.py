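"""Synthetic SNDS-like claims generator with planted ground truth.

The generator emulates the event structure the identification algorithms
consume: an age-sex-structured insured population observed 2006–2020, with

* myeloma onset following an age-increasing annual hazard, and three care
  pathways — hospital-treated (C90* positioned stay + MM-specific
  treatment), LTD-registered (C90* long-term-disease record + treatment,
  with the registration suppressed for a share of patients, reflecting the
  known under-reporting of the status), and oral-only patients managed on
  lenalidomide/thalidomide in retail pharmacy with protein-electrophoresis
  monitoring and no myeloma-coded stay or LTD record;
* *confuser* patients dispensed the same immunomodulatory drugs for a
  non-myeloma indication (myelodysplastic syndrome, lymphomas,
  myelofibrosis, amyloidosis …), always carrying a hospital stay coded with
  that indication so that the exclusion clause can reject them;
* excess mortality after onset, coverage gaps of two years or more, and a
  background stream of reimbursed events for every insured person.

Every person receives a :class:`TruthLabels` row carrying the true disease
status, onset date, pathway and — derived from the *final* event stream by
an independent per-person re-evaluation of the inclusion rules — the set
of algorithms designed to detect them (``designed_detectable_by``).

An adversarial mode replaces part of the population with a deterministic
battery of boundary cases (dispensings exactly 90 days apart, monitoring
events exactly at the window edge, age exactly at the adult threshold,
identification-window boundary dates, a rule-qualifying false positive …)
for oracle-equivalence testing; outside that mode the generator never
plants a person who qualifies under the oral rule without having myeloma.
"""

from __future__ import annotations

import datetime
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .claims import ClaimsDataset
from .codes import CodeListConfig, match_icd10
from .cohort import AlgorithmConfig

__all__ = ["SimulationConfig", "Band", "StratumShare", "simulate", "planted_rates"]

_DAY = "datetime64[D]"
_INF = np.iinfo(np.int64).max // 4


def _day(date_like) -> int:
    return np.datetime64(str(date_like), "D").astype(int)


def _year_start(y: int) -> int:
    return _day(f"{y}-01-01")


def _days_in_year(y: int) -> int:
    return _year_start(y + 1) - _year_start(y)


class Band(BaseModel):
    """An age band ``[age_lo, age_hi]`` carrying a per-year hazard."""

    age_lo: int
    age_hi: int
    value: float = Field(ge=0)


class StratumShare(BaseModel):
    age_lo: int
    age_hi: int
    sex: str
    share: float = Field(ge=0, le=1)


def _default_structure() -> list[StratumShare]:
    # crude western-European pyramid anchored at the 2014 study start
    rows = [
        (0, 17, 0.1122, 0.1078),
        (18, 39, 0.1350, 0.1350),
        (40, 54, 0.0990, 0.1010),
        (55, 64, 0.0582, 0.0618),
        (65, 74, 0.0470, 0.0530),
        (75, 84, 0.0258, 0.0342),
        (85, 99, 0.0102, 0.0198),
    ]
    out = []
    for lo, hi, m, f in rows:
        out.append(StratumShare(age_lo=lo, age_hi=hi, sex="male", share=m))
        out.append(StratumShare(age_lo=lo, age_hi=hi, sex="female", share=f))
    return out


def _default_incidence() -> list[Band]:
    # annual myeloma onset hazard; steeply age-increasing, ~3.6/100,000
    # once standardized to the world standard age distribution
    return [
        Band(age_lo=0, age_hi=17, value=0.0),
        Band(age_lo=18, age_hi=39, value=2e-6),
        Band(age_lo=40, age_hi=49, value=2e-5),
        Band(age_lo=50, age_hi=59, value=6e-5),
        Band(age_lo=60, age_hi=69, value=1.8e-4),
        Band(age_lo=70, age_hi=79, value=3.5e-4),
        Band(age_lo=80, age_hi=120, value=4.5e-4),
    ]


def _default_mortality() -> list[Band]:
    return [
        Band(age_lo=0, age_hi=39, value=5e-4),
        Band(age_lo=40, age_hi=49, value=2e-3),
        Band(age_lo=50, age_hi=59, value=5e-3),
        Band(age_lo=60, age_hi=69, value=1.2e-2),
        Band(age_lo=70, age_hi=79, value=3.0e-2),
        Band(age_lo=80, age_hi=120, value=9.0e-2),
    ]


class SimulationConfig(BaseModel):
    """Study conditions of a synthetic run; defaults are the package's
    reference scenario (documented in the methods note)."""

    n_persons: int = Field(gt=0)
    year_range: tuple[int, int] = (2006, 2020)
    reference_year: int = 2014  # year at which the age structure is anchored
    age_sex_structure: list[StratumShare] = Field(default_factory=_default_structure)
    mm_incidence_by_age: list[Band] = Field(default_factory=_default_incidence)
    background_mortality_by_age: list[Band] = Field(default_factory=_default_mortality)
    pathway_mix: dict[str, float] = Field(
        default_factory=lambda: {"hospital": 0.55, "ltd": 0.20, "oral_only": 0.25}
    )
    ltd_reporting_prob: float = Field(default=0.60, ge=0, le=1)
    confuser_rate: float = Field(default=0.002, ge=0, le=1)
    spep_monitoring_prob: float = Field(default=0.90, ge=0, le=1)
    mm_excess_mortality: float = Field(default=0.12, ge=0)
    coverage_gap_prob: float = Field(default=0.03, ge=0, le=1)
    background_reimbursement_rate: float = Field(default=4.0, ge=0)
    onset_treatment_delay_mean_days: float = Field(default=30.0, gt=0)
    lenalidomide_share: float = Field(default=0.7, ge=0, le=1)
    adversarial: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("degenerate year_range: last year precedes first")
        total = sum(s.share for s in self.age_sex_structure)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("age_sex_structure shares must sum to 1")
        mix = sum(self.pathway_mix.get(k, 0.0) for k in ("hospital", "ltd", "oral_only"))
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("pathway_mix must sum to 1 over hospital/ltd/oral_only")
        return self


def _band_lookup(bands: list[Band]):
    los = np.array([b.age_lo for b in bands])
    his = np.array([b.age_hi for b in bands])
    vals = np.array([b.value for b in bands])
    order = np.argsort(los)
    los, his, vals = los[order], his[order], vals[order]

    def lookup(ages: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(los, ages, side="right") - 1
        idx = np.clip(idx, 0, len(los) - 1)
        out = vals[idx]
        out = np.where((ages < los[0]) | (ages > his[idx]), 0.0, out)
        return out

    return lookup


# --------------------------------------------------------------------------
# adversarial boundary templates
# --------------------------------------------------------------------------
# event grammar: ("stay", off, icd, pos) ("ltd", off, icd) ("disp", off, drug_key)
# ("proc", off, proc_key) ("reimb", off); offsets in days from the template
# anchor, or absolute ISO dates (which disables jitter for that template).

def _adversarial_templates(cl: CodeListConfig) -> list[dict]:
    LEN = cl.lenalidomide_drugs[0]
    THA = cl.thalidomide_drugs[0]
    MM = cl.mm_specific_drugs[0]
    CHE = cl.chemotherapy_drugs[0]
    SP = cl.spep_procedures[0]
    UP = cl.upep_procedures[0]
    T: list[dict] = []

    def t(name, events, age=60, true_mm=False, pathway="none", confuser=None, jitter=True):
        T.append(dict(name=name, events=events, age=age, true_mm=true_mm,
                      pathway=pathway, confuser=confuser, jitter=jitter))

    t("oral_qualifies", [("disp", 0, LEN), ("disp", 60, LEN), ("proc", 30, SP), ("proc", 90, UP)],
      true_mm=True, pathway="oral_only")
    t("oral_exact_boundaries", [("disp", 0, LEN), ("disp", 90, LEN), ("proc", 0, SP), ("proc", 120, SP)],
      true_mm=True, pathway="oral_only")
    t("oral_pair_91_days", [("disp", 0, LEN), ("disp", 91, LEN), ("proc", 30, SP), ("proc", 60, SP)],
      true_mm=True, pathway="oral_only")
    t("oral_same_day_double", [("disp", 0, LEN), ("disp", 0, LEN), ("proc", 10, SP), ("proc", 20, SP)],
      true_mm=True, pathway="oral_only")
    t("oral_monitoring_at_121", [("disp", 0, LEN), ("disp", 45, LEN), ("proc", 30, SP), ("proc", 121, SP)],
      true_mm=True, pathway="oral_only")
    t("oral_single_monitoring", [("disp", 0, LEN), ("disp", 45, LEN), ("proc", 60, SP)],
      true_mm=True, pathway="oral_only")
    t("oral_blocked_by_exclusion", [("disp", 0, LEN), ("disp", 45, LEN), ("proc", 30, SP), ("proc", 60, SP),
                                    ("stay", -400, "D461", "PD")],
      confuser="D461")
    t("thalidomide_qualifies", [("disp", 0, THA), ("disp", 80, THA), ("proc", 10, UP), ("proc", 115, UP)],
      true_mm=True, pathway="oral_only")
    t("cross_drug_pair_fails", [("disp", 0, LEN), ("disp", 30, THA), ("disp", 200, LEN),
                                ("proc", 30, SP), ("proc", 60, SP)],
      true_mm=True, pathway="oral_only")
    t("hospital_arm", [("stay", -100, "C901", "SAD"), ("disp", 0, MM)], true_mm=True, pathway="hospital")
    t("untreated_ltd", [("ltd", 0, "C900")], true_mm=True, pathway="ltd")
    t("untreated_stay_2013", [("stay", "2013-06-01", "C900", "PD")], true_mm=True, pathway="hospital", jitter=False)
    t("treated_stay_2013", [("stay", "2013-06-01", "C900", "PD"), ("disp", "2013-07-01", CHE)],
      true_mm=True, pathway="hospital", jitter=False)
    t("age_exactly_18", [("stay", 0, "C900", "PD"), ("disp", 0, CHE)], age=18, true_mm=True, pathway="hospital")
    t("age_17_minor", [("stay", 0, "C900", "PD"), ("disp", 0, CHE)], age=17, true_mm=True, pathway="hospital")
    t("age_19", [("stay", 0, "C900", "PD"), ("disp", 0, CHE)], age=19, true_mm=True, pathway="hospital")
    t("stay_ltd_same_day_tie", [("stay", 0, "C902", "RD"), ("ltd", 0, "C900"), ("disp", 10, MM)],
      true_mm=True, pathway="hospital")
    t("treatment_only", [("disp", 0, MM), ("disp", 30, MM)], true_mm=True, pathway="hospital")
    t("oral_edges_age_18", [("disp", 0, LEN), ("disp", 90, LEN), ("proc", 0, SP), ("proc", 120, SP)],
      age=18, true_mm=True, pathway="oral_only")
    t("oral_false_positive", [("disp", 0, LEN), ("disp", 60, LEN), ("proc", 30, SP), ("proc", 60, SP)])
    t("ltd_arm", [("ltd", 0, "C900"), ("disp", 15, CHE)], true_mm=True, pathway="ltd")
    t("stay_day_before_palmaro_window", [("stay", "2013-12-31", "C900", "PD"), ("disp", "2014-06-01", CHE)],
      true_mm=True, pathway="hospital", jitter=False)
    t("untreated_stay_window_start", [("stay", "2014-01-01", "C905", "PD")], true_mm=True, pathway="hospital",
      jitter=False)
    t("oral_near_study_end", [("disp", "2020-11-30", LEN), ("disp", "2020-12-30", LEN),
                              ("proc", "2020-12-05", SP), ("proc", "2020-12-20", SP)],
      true_mm=True, pathway="oral_only", jitter=False)
    t("gap_censored_hospital_arm", [("stay", "2014-03-01", "C900", "PD"), ("disp", "2014-03-10", CHE),
                                    ("reimb", "2014-06-01"), ("reimb", "2017-01-01")],
      true_mm=True, pathway="hospital", jitter=False)
    return T


# --------------------------------------------------------------------------
# the generator
# --------------------------------------------------------------------------

class _EventStore:
    def __init__(self):
        self.stays: list[tuple] = []  # (pid, stay_id, day, icd, pos)
        self.ltd: list[tuple] = []  # (pid, day, icd)
        self.disp: list[tuple] = []  # (pid, day, drug_id)
        self.proc: list[tuple] = []  # (pid, day, code)
        self.reimb: list[tuple] = []  # (pid, day)
        self._stay_seq = 0

    def stay(self, pid, day, icd, pos):
        self._stay_seq += 1
        self.stays.append((pid, self._stay_seq, day, icd, pos))
        return self._stay_seq

    def stay_dx(self, pid, stay_id, day, icd, pos):
        self.stays.append((pid, stay_id, day, icd, pos))


def simulate(
    config: SimulationConfig, codelists: CodeListConfig | None = None
) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a claims dataset and its truth labels.

    Reproducible: identical config (including seed) yields identical output,
    row for row.  Returns ``(dataset, truth)`` where *truth* has one row per
    person with columns ``person_id, true_mm, onset_date, pathway,
    confuser_indication, designed_detectable_by, sex, birth_year,
    death_date`` (the demographic columns are copied in so the truth table
    is self-contained for rate oracles).
    """
    cl = codelists or CodeListConfig()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    y0, y1 = cfg.year_range
    obs_start = _year_start(y0)
    obs_end = _day(f"{y1}-12-31")
    years = list(range(y0, y1 + 1))

    # ---------------------------------------------------------- demographics
    shares = np.array([s.share for s in cfg.age_sex_structure])
    shares = shares / shares.sum()
    stratum = rng.choice(len(shares), size=n, p=shares)
    lo = np.array([s.age_lo for s in cfg.age_sex_structure])[stratum]
    hi = np.array([s.age_hi for s in cfg.age_sex_structure])[stratum]
    age_ref = lo + rng.integers(0, hi - lo + 1)
    sex = np.array([s.sex for s in cfg.age_sex_structure], dtype=object)[stratum]
    birth_year = cfg.reference_year - age_ref

    # ------------------------------------------------- adversarial templates
    templates = _adversarial_templates(cl) if cfg.adversarial else []
    n_adv = min(n, max(len(templates), n // 2)) if templates else 0
    template_of = np.full(n, -1)
    anchor_day = np.zeros(n, dtype=np.int64)
    if n_adv:
        base_anchor = _day("2016-03-01")
        for i in range(n_adv):
            k = i % len(templates)
            template_of[i] = k
            t = templates[k]
            jit = int(rng.integers(-300, 301)) if t["jitter"] else 0
            anchor_day[i] = base_anchor + jit
            anchor_year = np.datetime64(int(anchor_day[i]), "D").astype("datetime64[Y]").astype(int) + 1970
            birth_year[i] = anchor_year - t["age"]
            sex[i] = "male" if i % 2 == 0 else "female"
    is_template = template_of >= 0
    # in adversarial mode the natural remainder is densified so that
    # organically generated patients and confusers also appear
    inc_boost = 25.0 if cfg.adversarial else 1.0
    confuser_rate = min(1.0, cfg.confuser_rate * (10.0 if cfg.adversarial else 1.0))

    # ------------------------------------------- onset and death, year by year
    inc = _band_lookup(cfg.mm_incidence_by_age)
    mort = _band_lookup(cfg.background_mortality_by_age)
    onset_day = np.full(n, _INF, dtype=np.int64)
    death_day = np.full(n, _INF, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    natural = ~is_template
    for y in years:
        ages = y - birth_year
        ystart, ndays = _year_start(y), _days_in_year(y)
        at_risk = natural & alive & (onset_day == _INF)
        h = np.minimum(inc(ages) * inc_boost, 1.0)
        new = at_risk & (rng.random(n) < h)
        onset_day[new] = ystart + rng.integers(0, ndays, size=n)[new]
        h_d = mort(ages) + np.where(onset_day <= ystart + ndays, cfg.mm_excess_mortality, 0.0)
        dies = natural & alive & (rng.random(n) < np.minimum(h_d, 1.0))
        dd = ystart + rng.integers(0, ndays, size=n)
        dd = np.maximum(dd, np.where(onset_day < _INF, np.minimum(onset_day, ystart + ndays - 1), dd))
        death_day[dies] = dd[dies]
        alive[dies] = False
        onset_day[onset_day > death_day] = _INF  # onset drawn after death in same year

    has_mm = onset_day < _INF

    # -------------------------------------------------------- coverage gaps
    gap_start = np.full(n, _INF, dtype=np.int64)
    gap_end = np.full(n, -1, dtype=np.int64)
    gappy = natural & (rng.random(n) < cfg.coverage_gap_prob)
    g_len = (731 + rng.exponential(365, size=n)).astype(np.int64)
    g_start = obs_start + rng.integers(0, max(obs_end - obs_start, 1), size=n)
    gap_start[gappy] = g_start[gappy]
    gap_end[gappy] = (g_start + g_len)[gappy]

    # affiliation starts at birth for persons born inside the window
    birth_day = np.array([_year_start(int(b)) for b in birth_year])
    astart = np.maximum(obs_start, birth_day)

    store = _EventStore()
    truth_pathway = np.full(n, "none", dtype=object)
    confuser_code = np.full(n, None, dtype=object)

    # ------------------------------------------------------------ care events
    pw_names = ("hospital", "ltd", "oral_only")
    pw_p = np.array([cfg.pathway_mix[k] for k in pw_names])
    mm_idx = np.flatnonzero(has_mm)
    mm_codes = ["C900", "C901", "C902", "C905", "C909"]
    extra_dx = ["I10", "E119", "N179", "J449"]
    mean_delay = cfg.onset_treatment_delay_mean_days

    for i in mm_idx:
        pid = i + 1
        lim = min(death_day[i], obs_end)
        pw = pw_names[rng.choice(3, p=pw_p)]
        truth_pathway[i] = pw
        t0 = min(onset_day[i] + 1 + rng.geometric(1.0 / mean_delay), lim)

        if pw in ("hospital", "ltd"):
            reported_ltd = rng.random() < cfg.ltd_reporting_prob
            # an LTD-pathway patient whose registration is suppressed is
            # downgraded to hospital evidence so that treatment remains visible
            effective = pw if (pw != "ltd" or reported_ltd) else "hospital"
            if effective == "hospital":
                n_stays = 1 + rng.poisson(1.0)
                sday = t0
                for s in range(n_stays):
                    code = mm_codes[rng.choice(len(mm_codes))]
                    pos = ("PD", "RD", "SAD")[rng.choice(3, p=[0.7, 0.15, 0.15])]
                    sid = store.stay(pid, min(sday, lim), code, pos)
                    if rng.random() < 0.3:
                        store.stay_dx(pid, sid, min(sday, lim), extra_dx[rng.choice(len(extra_dx))], "SAD")
                    sday += rng.integers(60, 400)
                if pw == "hospital" and reported_ltd:
                    store.ltd.append((pid, min(t0 + rng.integers(0, 180), lim), "C900"))
            else:  # reported LTD, no myeloma-coded stay
                store.ltd.append((pid, min(t0 + rng.integers(0, 60), lim), "C900"))
            k = 4 + rng.poisson(4)
            d = t0
            for _ in range(k):
                pool = cl.chemotherapy_drugs if rng.random() < 0.3 else cl.mm_specific_drugs
                store.disp.append((pid, min(d, lim), pool[rng.choice(len(pool))]))
                d += rng.integers(21, 36)
            if (onset_day[i] - birth_day[i]) // 365 <= 65 and rng.random() < 0.3:
                store.proc.append((pid, min(t0 + 120, lim), cl.asct_procedures[0]))
            if rng.random() < 0.5:
                for _ in range(1 + rng.poisson(1)):
                    store.proc.append((pid, min(t0 + rng.integers(0, 365), lim), cl.spep_procedures[0]))
        else:  # oral_only: retail-pharmacy IMiD, no C90* stay, no LTD record
            drug = cl.lenalidomide_drugs[0] if rng.random() < cfg.lenalidomide_share else cl.thalidomide_drugs[0]
            k = 4 + rng.poisson(3)
            d = t0
            for _ in range(k):
                store.disp.append((pid, min(d, lim), drug))
                d += rng.integers(21, 61)
            if rng.random() < cfg.spep_monitoring_prob:
                p1 = min(t0 + rng.integers(0, 31), lim)
                p2 = min(t0 + rng.integers(35, 121), lim)
                store.proc.append((pid, p1, cl.spep_procedures[0]))
                kind2 = cl.upep_procedures[0] if rng.random() < 0.3 else cl.spep_procedures[0]
                store.proc.append((pid, p2, kind2))
                for _ in range(rng.poisson(1)):
                    store.proc.append((pid, min(t0 + rng.integers(121, 500), lim), cl.spep_procedures[0]))
            else:
                if rng.random() < 0.5:
                    store.proc.append((pid, min(t0 + rng.integers(0, 365), lim), cl.spep_procedures[0]))

    # ------------------------------------------------------------- confusers
    conf = natural & ~has_mm & (rng.random(n) < confuser_rate)
    exclusion_examples = ["D461", "C820", "C833", "C844", "C851", "D474", "C944", "E854"]
    for i in np.flatnonzero(conf):
        pid = i + 1
        lim = min(death_day[i], obs_end)
        span = max(int(lim - astart[i]), 1)
        c0 = astart[i] + rng.integers(0, span)
        code = exclusion_examples[rng.choice(len(exclusion_examples))]
        confuser_code[i] = code
        store.stay(pid, c0, code, "PD")
        drug = cl.lenalidomide_drugs[0] if rng.random() < 0.8 else cl.thalidomide_drugs[0]
        d = c0
        for _ in range(2 + rng.poisson(2)):
            store.disp.append((pid, min(d, lim), drug))
            d += rng.integers(21, 61)
        for _ in range(rng.integers(0, 3)):
            store.proc.append((pid, min(c0 + rng.integers(0, 120), lim), cl.spep_procedures[0]))

    # ------------------------------------------------------ template events
    for i in np.flatnonzero(is_template):
        pid = i + 1
        t = templates[template_of[i]]
        truth_pathway[i] = t["pathway"] if t["true_mm"] else "none"
        confuser_code[i] = t["confuser"]
        for ev in t["events"]:
            off = ev[1]
            day = _day(off) if isinstance(off, str) else anchor_day[i] + int(off)
            day = int(np.clip(day, obs_start, obs_end))
            if ev[0] == "stay":
                store.stay(pid, day, ev[2], ev[3])
            elif ev[0] == "ltd":
                store.ltd.append((pid, day, ev[2]))
            elif ev[0] == "disp":
                store.disp.append((pid, day, ev[2]))
            elif ev[0] == "proc":
                store.proc.append((pid, day, ev[2]))
            elif ev[0] == "reimb":
                store.reimb.append((pid, day))

    # ------------------------------------------------ background reimbursements
    # affiliation segments: coverage runs birth/window start → death/window
    # end, split in two around a coverage gap
    aend = np.minimum(obs_end + 1, np.where(death_day < _INF, death_day + 1, _INF))
    seg1_s = astart
    seg1_e = np.minimum(aend, np.where(gap_start < _INF, gap_start, aend))
    seg2_s = np.where(gap_end > 0, np.minimum(np.maximum(gap_end, astart), aend), aend)
    seg2_e = np.where(gap_end > 0, aend, seg2_s)
    bg_parts = []
    if cfg.background_reimbursement_rate > 0:
        for s, e in ((seg1_s, seg1_e), (seg2_s, seg2_e)):
            keep = (e > s) & ~is_template
            idx = np.flatnonzero(keep)
            if idx.size == 0:
                continue
            length = (e[idx] - s[idx]).astype(float)
            counts = rng.poisson(cfg.background_reimbursement_rate * length / 365.25)
            rep = np.repeat(idx, counts)
            u = rng.random(rep.size)
            days = (s[rep] + u * (e[rep] - s[rep])).astype(np.int64)
            bg_parts.append((rep + 1, days))

    # -------------------------------------------------------- assemble tables
    def _frame(rows, cols):
        return pd.DataFrame(rows, columns=cols)

    stays = _frame(store.stays, ["person_id", "stay_id", "day", "icd10_code", "position"])
    ltd = _frame(store.ltd, ["person_id", "day", "icd10_code"])
    disp = _frame(store.disp, ["person_id", "day", "drug_id"])
    proc = _frame(store.proc, ["person_id", "day", "procedure_code"])
    reimb_tmpl = _frame(store.reimb, ["person_id", "day"])
    reimb_parts = [reimb_tmpl] if len(reimb_tmpl) else []
    for pid_arr, day_arr in bg_parts:
        reimb_parts.append(pd.DataFrame({"person_id": pid_arr, "day": day_arr}))
    reimb = (
        pd.concat(reimb_parts, ignore_index=True)
        if reimb_parts
        else _frame([], ["person_id", "day"])
    )

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) == 0:
            return df
        i = df["person_id"].to_numpy(np.int64) - 1
        d = df["day"].to_numpy(np.int64)
        keep = (d >= astart[i]) & (d <= np.minimum(death_day[i], obs_end))
        keep &= ~((d >= gap_start[i]) & (d < gap_end[i]))
        return df.loc[keep].reset_index(drop=True)

    stays, ltd, disp, proc, reimb = map(_filter, (stays, ltd, disp, proc, reimb))

    # confuser safety: if filtering removed a confuser's exclusion stay but
    # left a qualifying monitoring pattern, thin their SPEP/UPEP events to one
    if not cfg.adversarial and confuser_code is not None:
        conf_ids = {i + 1 for i in np.flatnonzero(conf)}
        if conf_ids:
            has_stay = set(stays.loc[stays["person_id"].isin(conf_ids), "person_id"].unique())
            exposed = conf_ids - has_stay
            if exposed:
                m = proc["person_id"].isin(exposed)
                dup = m & proc.loc[m].groupby("person_id").cumcount().reindex(proc.index, fill_value=0).gt(0)
                proc = proc.loc[~dup].reset_index(drop=True)

    def _dt(df, col_in, col_out):
        df = df.copy()
        df[col_out] = pd.to_datetime(df[col_in].to_numpy(np.int64).astype(_DAY))
        return df.drop(columns=[col_in]) if col_in != col_out else df

    persons = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1, dtype=np.int64),
            "sex": sex,
            "birth_year": birth_year.astype(int),
            "death_date": pd.to_datetime(
                np.where(death_day < _INF, death_day, np.datetime64("NaT").astype(np.int64)).astype(_DAY)
            ),
        }
    )
    persons.loc[death_day >= _INF, "death_date"] = pd.NaT

    aff_rows = []
    for s, e in ((seg1_s, seg1_e), (seg2_s, seg2_e)):
        ok = e > s
        aff_rows.append(
            pd.DataFrame(
                {
                    "person_id": np.arange(1, n + 1, dtype=np.int64)[ok],
                    "start_date": pd.to_datetime(s[ok].astype(_DAY)),
                    "end_date": pd.to_datetime(np.minimum(e[ok], obs_end + 1).astype(_DAY)),
                }
            )
        )
    affiliations = (
        pd.concat(aff_rows, ignore_index=True)
        .drop_duplicates(["person_id", "start_date", "end_date"])
        .sort_values(["person_id", "start_date"])
        .reset_index(drop=True)
    )

    stays = _dt(stays.rename(columns={"day": "admission_date"}), "admission_date", "admission_date")
    ltd = _dt(ltd.rename(columns={"day": "registration_date"}), "registration_date", "registration_date")
    disp = _dt(disp.rename(columns={"day": "dispense_date"}), "dispense_date", "dispense_date")
    proc = _dt(proc.rename(columns={"day": "procedure_date"}), "procedure_date", "procedure_date")
    reimb = _dt(reimb.rename(columns={"day": "event_date"}), "event_date", "event_date")
    for df in (stays, ltd, disp, proc, reimb):
        df["person_id"] = df["person_id"].astype(np.int64)
    disp["drug_class"] = cl.classify_drug_ids(disp["drug_id"].astype(str)) if len(disp) else pd.Series(dtype=object)
    proc["kind"] = cl.classify_procedure_codes(proc["procedure_code"].astype(str)) if len(proc) else pd.Series(dtype=object)

    ds = ClaimsDataset(
        persons=persons,
        affiliations=affiliations,
        stays=stays.sort_values(["person_id", "admission_date", "stay_id"]).reset_index(drop=True),
        ltd_records=ltd.sort_values(["person_id", "registration_date"]).reset_index(drop=True),
        dispensings=disp.sort_values(["person_id", "dispense_date", "drug_id"]).reset_index(drop=True),
        procedures=proc.sort_values(["person_id", "procedure_date", "procedure_code"]).reset_index(drop=True),
        reimbursements=reimb.sort_values(["person_id", "event_date"]).reset_index(drop=True),
        observation_start=pd.Timestamp(np.datetime64(int(obs_start), "D")),
        observation_end=pd.Timestamp(np.datetime64(int(obs_end), "D")),
    )

    template_true = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(is_template):
        template_true[i] = bool(templates[template_of[i]]["true_mm"])
    truth = pd.DataFrame(
        {
            "person_id": persons["person_id"],
            "true_mm": has_mm | template_true,
            "onset_date": pd.to_datetime(
                np.where(onset_day < _INF, onset_day, np.datetime64("NaT").astype(np.int64)).astype(_DAY)
            ),
            "pathway": truth_pathway,
            "confuser_indication": confuser_code,
            "sex": persons["sex"],
            "birth_year": persons["birth_year"],
            "death_date": persons["death_date"],
        }
    )
    truth.loc[onset_day >= _INF, "onset_date"] = pd.NaT
    # template persons: onset = first planted event date
    for i in np.flatnonzero(is_template):
        if templates[template_of[i]]["true_mm"]:
            pid = i + 1
            cand = []
            for tab, col in ((ds.stays, "admission_date"), (ds.ltd_records, "registration_date"),
                             (ds.dispensings, "dispense_date"), (ds.procedures, "procedure_date")):
                sub = tab.loc[tab["person_id"] == pid, col]
                if len(sub):
                    cand.append(sub.min())
            truth.loc[i, "onset_date"] = min(cand) if cand else pd.NaT

    truth["designed_detectable_by"] = _detectability(ds, cl)
    return ds, truth


# --------------------------------------------------------------------------
# independent per-person rule re-evaluation (construction soundness)
# --------------------------------------------------------------------------

def _detectability(ds: ClaimsDataset, cl: CodeListConfig) -> pd.Series:
    """Per-person ``designed_detectable_by`` strings (``;``-joined, sorted),
    derived from the final event stream by a plain-loop re-evaluation of the
    inclusion rules (kept deliberately separate from the vectorized
    implementations in :mod:`mmepi.cohort`)."""
    my = AlgorithmConfig.mylord()
    pa = AlgorithmConfig.palmaro("base")

    active = set()
    for tab in (ds.stays, ds.ltd_records, ds.dispensings):
        active.update(tab["person_id"].unique())
    active.update(ds.procedures.loc[ds.procedures["kind"] == "ASCT", "person_id"].unique())

    by = ds.persons.set_index("person_id")["birth_year"]
    stays_by = dict(iter(ds.stays.groupby("person_id"))) if len(ds.stays) else {}
    ltd_by = dict(iter(ds.ltd_records.groupby("person_id"))) if len(ds.ltd_records) else {}
    disp_by = dict(iter(ds.dispensings.groupby("person_id"))) if len(ds.dispensings) else {}
    proc_by = dict(iter(ds.procedures.groupby("person_id"))) if len(ds.procedures) else {}

    out = pd.Series("", index=ds.persons["person_id"].to_numpy(), dtype=object)
    for pid in sorted(active):
        st = stays_by.get(pid)
        lt = ltd_by.get(pid)
        dp = disp_by.get(pid)
        pr = proc_by.get(pid)
        stay_rows = list(zip(st["admission_date"], st["icd10_code"])) if st is not None else []
        ltd_rows = list(zip(lt["registration_date"], lt["icd10_code"])) if lt is not None else []
        disp_rows = list(zip(dp["dispense_date"], dp["drug_class"])) if dp is not None else []
        proc_rows = list(zip(pr["procedure_date"], pr["kind"])) if pr is not None else []
        labels = set()
        if _plain_mylord(stay_rows, ltd_rows, disp_rows, proc_rows, int(by[pid]), my, cl):
            labels.add("mylord")
        if _plain_palmaro(stay_rows, ltd_rows, disp_rows, proc_rows, int(by[pid]), pa, cl, treated=False):
            labels.add("palmaro")
        if _plain_palmaro(stay_rows, ltd_rows, disp_rows, proc_rows, int(by[pid]), pa, cl, treated=True):
            labels.add("palmaro_treated")
        out[pid] = ";".join(sorted(labels))
    return out.to_numpy()


def _in(day, lo, hi):
    return lo <= day <= hi


def _plain_mylord(stays, ltds, disps, procs, birth_year, cfg: AlgorithmConfig, cl: CodeListConfig) -> bool:
    lo, hi = pd.Timestamp(cfg.identification_start), pd.Timestamp(cfg.identification_end)
    stay_dates = sorted(d for d, c in stays if any(match_icd10(c, p) for p in cl.mm_icd10) and _in(d, lo, hi))
    ltd_dates = sorted(d for d, c in ltds if any(match_icd10(c, p) for p in cl.mm_icd10) and _in(d, lo, hi))
    treat_dates = sorted(
        [d for d, c in disps if c in ("mm_specific", "chemotherapy") and _in(d, lo, hi)]
        + [d for d, k in procs if k == "ASCT" and _in(d, lo, hi)]
    )
    firsts = []
    if (stay_dates or ltd_dates) and treat_dates:
        firsts.extend([x for x in (stay_dates[:1] + ltd_dates[:1] + treat_dates[:1])])
    excluded = any(any(match_icd10(c, p) for p in cl.exclusion_icd10) for _, c in stays)
    if not excluded:
        for drug in ("lenalidomide", "thalidomide"):
            dates = sorted({d for d, c in disps if c == drug and _in(d, lo, hi)})
            if len(dates) < 2:
                continue
            if min((b - a).days for a, b in zip(dates, dates[1:])) > cfg.imid_repeat_window_days:
                continue
            d0 = dates[0]
            wend = d0 + pd.Timedelta(days=cfg.monitoring_window_days)
            nmon = sum(1 for d, k in procs if k in ("SPEP", "UPEP") and d0 <= d <= wend)
            if nmon >= 2:
                firsts.append(d0)
    if not firsts:
        return False
    first = min(firsts)
    return first.year - birth_year >= cfg.adult_age_min


def _plain_palmaro(stays, ltds, disps, procs, birth_year, cfg: AlgorithmConfig, cl: CodeListConfig, treated: bool) -> bool:
    lo, hi = pd.Timestamp(cfg.identification_start), pd.Timestamp(cfg.identification_end)
    stay_dates = sorted(d for d, c in stays if any(match_icd10(c, p) for p in cl.mm_icd10) and _in(d, lo, hi))
    ltd_dates = sorted(d for d, c in ltds if any(match_icd10(c, p) for p in cl.mm_icd10) and _in(d, lo, hi))
    if not (stay_dates or ltd_dates):
        return False
    if treated:
        treat = [d for d, c in disps if c in ("mm_specific", "chemotherapy") and _in(d, lo, hi)]
        treat += [d for d, k in procs if k == "ASCT" and _in(d, lo, hi)]
        if not treat:
            return False
    first = min(stay_dates[:1] + ltd_dates[:1])
    return first.year - birth_year > cfg.adult_age_min


# --------------------------------------------------------------------------
# planted-rate oracle
# --------------------------------------------------------------------------

def planted_rates(
    truth: pd.DataFrame,
    config: SimulationConfig,
    year: int,
    age_groups: Optional[list[tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Empirical planted incidence per age group for one calendar year.

    Counts onsets in *year* over persons alive and onset-free on January 1
    (a point-in-time at-risk denominator, matching the convention the
    indicator pipeline uses for its rate denominators).  Computed directly
    from the truth labels, independent of any identification step.
    """
    y0, y1 = config.year_range
    if not (y0 <= year <= y1):
        raise ValueError(f"year {year} outside simulated range {config.year_range}")
    if age_groups is None:
        from .indicators import SEGI_AGE_GROUPS

        age_groups = SEGI_AGE_GROUPS
    jan1 = pd.Timestamp(year=year, month=1, day=1)
    age = year - truth["birth_year"]
    alive = truth["death_date"].isna() | (truth["death_date"] >= jan1)
    onset_free = truth["onset_date"].isna() | (truth["onset_date"] >= jan1)
    at_risk = alive & onset_free & (age >= 0)
    onsets_in_year = truth["onset_date"].dt.year.eq(year)

    rows = []
    for glo, ghi in age_groups:
        in_group = (age >= glo) & (age <= ghi)
        n_risk = int((at_risk & in_group).sum())
        n_onset = int((at_risk & in_group & onsets_in_year).sum())
        rows.append((glo, ghi, n_onset, n_risk, n_onset / n_risk if n_risk else 0.0))
    return pd.DataFrame(rows, columns=["age_lo", "age_hi", "onsets", "at_risk", "rate"])
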