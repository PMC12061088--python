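"""Yearly indicators: counts, crude rates, direct standardization, extrapolation.

Definitions follow the claims-cohort conventions: prevalence in year Y
counts cohort members under follow-up on January 1 of Y (followup started
on or before that day, alive — a death on January 1 itself still counts as
alive that day — affiliated, and not yet censored); incidence counts
members whose incident year is Y; mortality counts members whose follow-up
ended in death during Y (deaths occurring after gap censoring are not
counted — the member has left observation).  Crude rates divide by the
affiliated population of the corresponding year (a point-in-time January-1
headcount used as the person-year denominator) per 100,000.  Direct
standardization weights the per-age-group rates by a standard age
distribution — by default the Segi world standard in 5-year groups — with
gamma (Fay–Feuer) or normal confidence intervals; the same age standard is
applied within each sex for sex-stratified rates.  Ages are
analysis-year − birth_year, binned on January 1 for prevalence/mortality
and in the incidence year for incidence.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims import ClaimsDataset

__all__ = [
    "StandardPopulation",
    "SEGI_AGE_GROUPS",
    "segi_world",
    "build_denominators",
    "count_prevalent",
    "count_incident",
    "count_deaths",
    "crude_rate",
    "direct_standardize",
    "extrapolate",
    "build_rate_table",
    "UndefinedRateError",
]


class UndefinedRateError(ValueError):
    """A rate with events but a zero population denominator."""


# Segi (1960) world standard population, 5-year age groups, per 100,000
_SEGI = [
    (0, 4, 12000), (5, 9, 10000), (10, 14, 9000), (15, 19, 9000),
    (20, 24, 8000), (25, 29, 8000), (30, 34, 6000), (35, 39, 6000),
    (40, 44, 6000), (45, 49, 6000), (50, 54, 5000), (55, 59, 4000),
    (60, 64, 4000), (65, 69, 3000), (70, 74, 2000), (75, 79, 1000),
    (80, 84, 500), (85, 120, 500),
]
SEGI_AGE_GROUPS: list[tuple[int, int]] = [(lo, hi) for lo, hi, _ in _SEGI]


@dataclasses.dataclass(frozen=True)
class StandardPopulation:
    """Ordered, contiguous age groups with weights summing to one."""

    age_groups: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.age_groups) != len(self.weights):
            raise ValueError("age_groups and weights must align")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        for (lo1, hi1), (lo2, _) in zip(self.age_groups, self.age_groups[1:]):
            if lo2 != hi1 + 1:
                raise ValueError("age groups must be contiguous and non-overlapping")

    def group_labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.age_groups]

    def bin_ages(self, ages: np.ndarray) -> np.ndarray:
        """Index of the age group containing each age (-1 when outside)."""
        los = np.array([lo for lo, _ in self.age_groups])
        his = np.array([hi for _, hi in self.age_groups])
        idx = np.searchsorted(los, ages, side="right") - 1
        idx = np.clip(idx, 0, len(los) - 1)
        bad = (ages < los[0]) | (ages > his[idx])
        return np.where(bad, -1, idx)

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        df = pd.read_csv(path)
        w = df["weight"].to_numpy(float)
        return cls(tuple(zip(df["age_lo"].astype(int), df["age_hi"].astype(int))), tuple(w / w.sum()))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "age_lo": [lo for lo, _ in self.age_groups],
                "age_hi": [hi for _, hi in self.age_groups],
                "weight": self.weights,
            }
        ).to_csv(path, index=False)


def segi_world() -> StandardPopulation:
    total = sum(w for _, _, w in _SEGI)
    return StandardPopulation(
        tuple((lo, hi) for lo, hi, _ in _SEGI), tuple(w / total for _, _, w in _SEGI)
    )


# --------------------------------------------------------------------------
# denominators and stratified counts
# --------------------------------------------------------------------------

def _jan1(year: int) -> pd.Timestamp:
    return pd.Timestamp(year=year, month=1, day=1)


def affiliated_on(affiliations: pd.DataFrame, date: pd.Timestamp) -> pd.Series:
    """Set of person_ids covered on *date* (intervals half-open)."""
    m = (affiliations["start_date"] <= date) & (date < affiliations["end_date"])
    return affiliations.loc[m, "person_id"]


def _stratified(persons: pd.DataFrame, ids: Iterable[int], year: int, standard: StandardPopulation) -> pd.DataFrame:
    sub = persons[persons["person_id"].isin(pd.Index(ids))]
    ages = (year - sub["birth_year"]).to_numpy()
    gidx = standard.bin_ages(ages)
    df = pd.DataFrame({"group": gidx, "sex": sub["sex"].to_numpy()})
    df = df[df["group"] >= 0]
    counts = df.groupby(["group", "sex"]).size()
    full = pd.MultiIndex.from_product(
        [range(len(standard.age_groups)), ["male", "female"]], names=["group", "sex"]
    )
    out = counts.reindex(full, fill_value=0).reset_index(name="count")
    out["age_lo"] = [standard.age_groups[g][0] for g in out["group"]]
    out["age_hi"] = [standard.age_groups[g][1] for g in out["group"]]
    return out[["group", "age_lo", "age_hi", "sex", "count"]]


def build_denominators(
    ds: ClaimsDataset, years: Sequence[int], standard: StandardPopulation
) -> pd.DataFrame:
    """Affiliated-population headcounts per year × age group × sex
    (persons alive and covered on January 1 of the year)."""
    out = []
    for year in years:
        jan1 = _jan1(year)
        alive = ds.persons["death_date"].isna() | (ds.persons["death_date"] >= jan1)
        alive_ids = set(ds.persons.loc[alive, "person_id"])
        cov_ids = set(affiliated_on(ds.affiliations, jan1))
        strat = _stratified(ds.persons, alive_ids & cov_ids, year, standard)
        strat["year"] = year
        out.append(strat)
    df = pd.concat(out, ignore_index=True)
    return df.rename(columns={"count": "population"})


def _check_year(year: int, years: Sequence[int]) -> None:
    if year not in list(years):
        raise ValueError(f"year {year} outside analysis years {list(years)[0]}–{list(years)[-1]}")


def count_prevalent(
    followup: pd.DataFrame,
    ds: ClaimsDataset,
    year: int,
    standard: StandardPopulation,
    years: Sequence[int] = range(2014, 2021),
) -> pd.DataFrame:
    """Members under follow-up, alive and affiliated on January 1 of *year*,
    per age group × sex."""
    _check_year(year, years)
    jan1 = _jan1(year)
    fu = followup.merge(ds.persons[["person_id", "death_date"]], on="person_id", how="left")
    m = (fu["followup_start"] <= jan1) & (jan1 <= fu["followup_end"])
    m &= fu["death_date"].isna() | (fu["death_date"] >= jan1)
    ids = set(fu.loc[m, "person_id"]) & set(affiliated_on(ds.affiliations, jan1))
    return _stratified(ds.persons, ids, year, standard)


def count_incident(
    followup: pd.DataFrame,
    ds: ClaimsDataset,
    year: int,
    standard: StandardPopulation,
) -> pd.DataFrame:
    """Members newly included (incident) in *year*, per age group × sex,
    ages taken in the incidence year."""
    ids = followup.loc[followup["incident_year"].eq(year).fillna(False), "person_id"]
    return _stratified(ds.persons, ids, year, standard)


def count_deaths(
    followup: pd.DataFrame,
    ds: ClaimsDataset,
    year: int,
    standard: StandardPopulation,
) -> pd.DataFrame:
    """Members whose follow-up ended in death during *year*."""
    fu = followup.merge(ds.persons[["person_id", "death_date"]], on="person_id", how="left")
    m = (fu["end_reason"] == "death") & fu["death_date"].dt.year.eq(year)
    return _stratified(ds.persons, fu.loc[m, "person_id"], year, standard)


# --------------------------------------------------------------------------
# rates
# --------------------------------------------------------------------------

def crude_rate(count: float, population: float, scale: float = 100_000.0) -> float:
    """Events per *scale* population; 0/0 yields 0 with a warning."""
    if population == 0:
        if count == 0:
            import warnings

            warnings.warn("crude_rate: 0/0 treated as 0", RuntimeWarning, stacklevel=2)
            return 0.0
        raise UndefinedRateError("nonzero events with zero population")
    return count / population * scale


def direct_standardize(
    counts: Sequence[float],
    populations: Sequence[float],
    weights: Sequence[float],
    ci_method: str = "gamma",
    scale: float = 100_000.0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Directly standardized rate with confidence interval.

    ASR = Σᵢ wᵢ·(xᵢ/nᵢ)·scale, counts treated as Poisson.  ``ci_method``
    is ``gamma`` (Fay & Feuer 1997) or ``normal``
    (ASR ± z·√(Σ wᵢ² xᵢ/nᵢ²)·scale).  Strata with nᵢ = 0 and xᵢ = 0 carry
    no information and are skipped; nᵢ = 0 with xᵢ > 0 is an error.
    """
    x = np.asarray(counts, float)
    nn = np.asarray(populations, float)
    w = np.asarray(weights, float)
    if np.isnan(x).any() or np.isnan(nn).any():
        bad = int(np.flatnonzero(np.isnan(x) | np.isnan(nn))[0])
        raise ValueError(f"missing stratum at index {bad}")
    if ((nn == 0) & (x > 0)).any():
        raise UndefinedRateError("stratum with events but zero population")
    keep = nn > 0
    x, nn, w = x[keep], nn[keep], w[keep]

    mu = float(np.sum(w * x / nn))
    var = float(np.sum(w**2 * x / nn**2))
    z = stats.norm.ppf(1 - alpha / 2)

    if ci_method == "normal":
        half = z * math.sqrt(var)
        lo, hi = max(mu - half, 0.0), mu + half
    elif ci_method == "gamma":
        if mu > 0:
            lo = stats.gamma.ppf(alpha / 2, a=mu**2 / var, scale=var / mu) if var > 0 else mu
        else:
            lo = 0.0
        wM = float(np.max(w / nn)) if len(nn) else 0.0
        mu2, var2 = mu + wM, var + wM**2
        hi = stats.gamma.ppf(1 - alpha / 2, a=mu2**2 / var2, scale=var2 / mu2) if var2 > 0 else mu
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return mu * scale, lo * scale, hi * scale


def extrapolate(
    counts: pd.DataFrame,
    scheme_population: pd.DataFrame,
    target_population: pd.DataFrame,
    on: Sequence[str] = ("age_lo", "age_hi", "sex"),
) -> float:
    """Scale per-stratum cohort counts from the insured-scheme population to
    a target population: total = Σₛ countₛ · targetₛ / schemeₛ."""
    on = list(on)
    merged = counts.merge(
        scheme_population.rename(columns={"population": "scheme_pop"})[on + ["scheme_pop"]], on=on
    ).merge(
        target_population.rename(columns={"population": "target_pop"})[on + ["target_pop"]], on=on
    )
    if len(merged) < len(counts):
        raise ValueError("strata do not align across counts, scheme and target tables")
    bad = (merged["scheme_pop"] == 0) & (merged["count"] > 0)
    if bad.any():
        raise UndefinedRateError("stratum with cohort members but zero scheme population")
    m = merged[merged["scheme_pop"] > 0]
    return float((m["count"] * m["target_pop"] / m["scheme_pop"]).sum())


# --------------------------------------------------------------------------
# the yearly rate table
# --------------------------------------------------------------------------

_COUNTERS = {"incidence": count_incident, "prevalence": count_prevalent, "mortality": count_deaths}


def build_rate_table(
    followup: pd.DataFrame,
    ds: ClaimsDataset,
    denominators: pd.DataFrame,
    standard: StandardPopulation,
    years: Sequence[int] = range(2014, 2021),
    measures: Sequence[str] = ("incidence", "prevalence", "mortality"),
    ci_method: str = "gamma",
) -> pd.DataFrame:
    """Tidy per-year table of counts, crude rates and ASRs with CIs,
    overall and per sex."""
    rows = []
    for measure in measures:
        counter = _COUNTERS[measure]
        for year in years:
            if measure == "prevalence":
                strat = counter(followup, ds, year, standard, years=years)
            else:
                strat = counter(followup, ds, year, standard)
            den = denominators[denominators["year"] == year]
            merged = strat.merge(
                den[["group", "sex", "population"]], on=["group", "sex"], how="left"
            )
            for sexsel in ("all", "male", "female"):
                sub = merged if sexsel == "all" else merged[merged["sex"] == sexsel]
                agg = sub.groupby("group").agg(count=("count", "sum"), population=("population", "sum"))
                agg = agg.reindex(range(len(standard.age_groups)), fill_value=0)
                total = int(agg["count"].sum())
                pop = float(agg["population"].sum())
                cr = crude_rate(total, pop) if pop > 0 else 0.0
                asr, lo, hi = direct_standardize(
                    agg["count"], agg["population"], standard.weights, ci_method=ci_method
                )
                rows.append((measure, year, sexsel, total, pop, cr, asr, lo, hi))
    return pd.DataFrame(
        rows,
        columns=[
            "measure", "year", "sex", "count", "population",
            "crude_rate", "asr", "asr_ci_low", "asr_ci_high",
        ],
    )
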