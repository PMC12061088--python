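import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from factories import MM_DRUG, make_dataset
from mmepi.cohort import identify_mylord
from mmepi.followup import build_followup
from mmepi.indicators import (
    StandardPopulation,
    UndefinedRateError,
    build_denominators,
    build_rate_table,
    count_deaths,
    count_incident,
    count_prevalent,
    crude_rate,
    direct_standardize,
    extrapolate,
    segi_world,
)
from oracles import brute_asr

YEARS = list(range(2014, 2021))


def _std2():
    return StandardPopulation(((0, 59), (60, 120)), (0.6, 0.4))


# --------------------------------------------------------------------- counts

@pytest.fixture()
def cohort_ds(codelists):
    ds = make_dataset(
        persons=[
            (1, "male", 1950),                # included 2014, survives
            (2, "female", 1945, "2015-06-15"),  # included 2015-03, dies 2015-06
            (3, "male", 1938),                # included 2015, gap-censored 2016
        ],
        stays=[
            (1, "2014-02-01", "C900", "PD"),
            (2, "2015-03-01", "C901", "PD"),
            (3, "2015-04-01", "C902", "PD"),
        ],
        disp=[
            (1, "2014-02-10", MM_DRUG),
            (2, "2015-03-10", MM_DRUG),
            (3, "2015-04-10", MM_DRUG),
        ],
        reimb=[(1, f"{y}-06-01") for y in range(2014, 2021)] + [(3, "2016-02-01")],
    )
    cohort = identify_mylord(ds, codelists=codelists)
    fu = build_followup(ds, cohort, codelists)
    return ds, fu


def test_prevalence_counts_members_alive_on_jan1(cohort_ds):
    ds, fu = cohort_ds
    std = segi_world()
    # 2015: member 1 only; 2016: members 1 and 3; 2017: gap-censoring has
    # removed member 3; member 2 (died within the inclusion year) never counts
    for year, expected in ((2015, 1), (2016, 2), (2017, 1)):
        got = count_prevalent(fu, ds, year, std)["count"].sum()
        assert got == expected, year


def test_prevalence_rejects_year_outside_range(cohort_ds):
    ds, fu = cohort_ds
    with pytest.raises(ValueError, match="outside"):
        count_prevalent(fu, ds, 2005, segi_world(), years=YEARS)


def test_gap_censored_member_leaves_prevalence(cohort_ds):
    ds, fu = cohort_ds
    fu = fu.set_index("person_id")
    assert fu.loc[3, "end_reason"] == "reimbursement_gap"
    std = segi_world()
    assert count_prevalent(fu.reset_index(), ds, 2018, std)["count"].sum() == 1  # only member 1


def test_incident_counts_partition_members(cohort_ds):
    ds, fu = cohort_ds
    std = segi_world()
    total = sum(count_incident(fu, ds, y, std)["count"].sum() for y in YEARS)
    assert total == fu["incident_year"].notna().sum()
    assert count_incident(fu, ds, 2014, std)["count"].sum() == 1
    assert count_incident(fu, ds, 2015, std)["count"].sum() == 2


def test_death_counts(cohort_ds):
    ds, fu = cohort_ds
    std = segi_world()
    assert count_deaths(fu, ds, 2015, std)["count"].sum() == 1
    assert sum(count_deaths(fu, ds, y, std)["count"].sum() for y in YEARS) == 1


# ---------------------------------------------------------------- crude rates

@pytest.mark.parametrize("count,pop,expected", [(5, 100_000, 5.0), (0, 100_000, 0.0), (7, 35_000, 20.0)])
def test_crude_rate_arithmetic(count, pop, expected):
    assert crude_rate(count, pop) == pytest.approx(expected)


def test_crude_rate_degenerate_cases():
    with pytest.raises(UndefinedRateError):
        crude_rate(3, 0)
    with pytest.warns(RuntimeWarning):
        assert crude_rate(0, 0) == 0.0


# ------------------------------------------------------------- standardization

def test_asr_weighted_mean_example():
    # strata rates 10 and 20 per 100,000, weights 0.6/0.4 → 14.0
    asr, lo, hi = direct_standardize([10, 20], [100_000, 100_000], [0.6, 0.4])
    assert asr == pytest.approx(14.0)
    assert lo <= asr <= hi


def test_asr_identity_when_rates_equal():
    asr, *_ = direct_standardize([5, 50], [10_000, 100_000], [0.3, 0.7])
    assert asr == pytest.approx(50.0)


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=500),
            st.integers(min_value=1, max_value=10**6),
            st.floats(min_value=1e-6, max_value=1.0),
        ),
        min_size=2,
        max_size=8,
    )
)
def test_asr_matches_term_by_term_oracle(strata):
    counts = [s[0] for s in strata]
    pops = [s[1] for s in strata]
    w = np.array([s[2] for s in strata])
    w = w / w.sum()
    asr, _, _ = direct_standardize(counts, pops, w)
    assert asr == pytest.approx(brute_asr(counts, pops, w), rel=1e-12)


def test_asr_equals_crude_rate_under_own_age_distribution():
    pops = np.array([40_000.0, 35_000.0, 25_000.0])
    counts = np.array([4.0, 12.0, 30.0])
    weights = pops / pops.sum()
    asr, _, _ = direct_standardize(counts, pops, weights)
    assert asr == pytest.approx(crude_rate(counts.sum(), pops.sum()))


def test_asr_invariant_under_merging_equal_rate_strata():
    counts, pops = [10, 20, 7], [100_000, 200_000, 50_000]  # strata 1+2 share rate 1e-4
    w = [0.3, 0.5, 0.2]
    asr1, _, _ = direct_standardize(counts, pops, w)
    asr2, _, _ = direct_standardize([30, 7], [300_000, 50_000], [0.8, 0.2])
    assert asr1 == pytest.approx(asr2)


def test_missing_stratum_and_zero_population_errors():
    with pytest.raises(ValueError, match="missing"):
        direct_standardize([1, np.nan], [10, 10], [0.5, 0.5])
    with pytest.raises(UndefinedRateError):
        direct_standardize([1, 2], [10, 0], [0.5, 0.5])


def test_gamma_and_normal_intervals_contain_asr_and_agree_when_counts_large():
    counts = [150, 220, 310]
    pops = [1_000_000, 900_000, 800_000]
    w = [0.5, 0.3, 0.2]
    asr_g, lo_g, hi_g = direct_standardize(counts, pops, w, ci_method="gamma")
    asr_n, lo_n, hi_n = direct_standardize(counts, pops, w, ci_method="normal")
    assert asr_g == asr_n
    assert lo_g <= asr_g <= hi_g and lo_n <= asr_n <= hi_n
    width_g, width_n = hi_g - lo_g, hi_n - lo_n
    assert abs(width_g - width_n) / width_n < 0.05


def test_standard_population_validation():
    with pytest.raises(ValueError, match="sum"):
        StandardPopulation(((0, 59), (60, 120)), (0.6, 0.5))
    with pytest.raises(ValueError, match="contiguous"):
        StandardPopulation(((0, 59), (65, 120)), (0.6, 0.4))
    segi = segi_world()
    assert sum(segi.weights) == pytest.approx(1.0, abs=1e-12)
    assert len(segi.age_groups) == 18


# --------------------------------------------------------------- extrapolation

def test_extrapolate_single_stratum():
    counts = pd.DataFrame({"age_lo": [60], "age_hi": [120], "sex": ["male"], "count": [10]})
    scheme = counts.assign(population=[76]).drop(columns="count")
    target = counts.assign(population=[100]).drop(columns="count")
    assert extrapolate(counts, scheme, target) == pytest.approx(10 * 100 / 76)


def test_extrapolate_identity_when_target_equals_scheme():
    counts = pd.DataFrame(
        {"age_lo": [0, 60], "age_hi": [59, 120], "sex": ["male", "male"], "count": [5, 9]}
    )
    pop = counts.assign(population=[1000, 2000]).drop(columns="count")
    assert extrapolate(counts, pop, pop) == pytest.approx(14.0)


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=100),
            st.integers(min_value=1, max_value=10_000),
            st.integers(min_value=1, max_value=10_000),
        ),
        min_size=1,
        max_size=6,
    )
)
def test_extrapolate_matches_per_stratum_summation(strata):
    counts = pd.DataFrame(
        {
            "age_lo": range(len(strata)),
            "age_hi": range(len(strata)),
            "sex": ["male"] * len(strata),
            "count": [s[0] for s in strata],
        }
    )
    scheme = counts.assign(population=[s[1] for s in strata]).drop(columns="count")
    target = counts.assign(population=[s[2] for s in strata]).drop(columns="count")
    want = sum(c * t / s for c, s, t in strata)
    assert extrapolate(counts, scheme, target) == pytest.approx(want)


# ------------------------------------------------------------------ rate table

def test_rate_table_shape_and_consistency(small_sim, codelists):
    ds, _, _ = small_sim
    cohort = identify_mylord(ds, codelists=codelists)
    fu = build_followup(ds, cohort, codelists)
    std = segi_world()
    den = build_denominators(ds, YEARS, std)
    rates = build_rate_table(fu, ds, den, std, YEARS)
    assert set(rates["measure"]) == {"incidence", "prevalence", "mortality"}
    assert set(rates["sex"]) == {"all", "male", "female"}
    assert (rates["asr_ci_low"] <= rates["asr"] + 1e-12).all()
    assert (rates["asr"] <= rates["asr_ci_high"] + 1e-12).all()
    # sex-specific counts add up to the total
    for measure in ("incidence", "prevalence", "mortality"):
        sub = rates[rates["measure"] == measure].pivot(index="year", columns="sex", values="count")
        assert (sub["male"] + sub["female"] == sub["all"]).all()
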