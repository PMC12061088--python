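import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from factories import CHEMO, MM_DRUG, make_dataset
from mmepi.followup import (
    FollowupConfig,
    assign_index_date,
    build_followup,
    classify_incident,
    compute_followup_end,
)
from mmepi.cohort import identify_mylord
from oracles import brute_incident_year

CFG = FollowupConfig()

date_st = st.dates(min_value=pd.Timestamp("2006-01-01").date(), max_value=pd.Timestamp("2020-12-31").date())


class TestIndexDate:
    def test_first_in_study_treatment(self):
        assert assign_index_date([pd.Timestamp("2015-03-10")], CFG) == pd.Timestamp("2015-03-10")

    def test_pre_2014_treatment_anchors_at_study_start(self):
        got = assign_index_date([pd.Timestamp("2012-05-01"), pd.Timestamp("2015-03-10")], CFG)
        assert got == pd.Timestamp("2014-01-01")

    def test_treatment_exactly_on_study_start(self):
        assert assign_index_date([pd.Timestamp("2014-01-01")], CFG) == pd.Timestamp("2014-01-01")

    def test_untreated_member_requires_fallback(self):
        with pytest.raises(ValueError, match="no treatment"):
            assign_index_date([], CFG)
        assert assign_index_date([], CFG, fallback=pd.Timestamp("2016-02-01")) == pd.Timestamp("2016-02-01")


class TestClassifyIncident:
    def test_clean_history_is_incident(self):
        assert classify_incident([pd.Timestamp("2016-03-01")], CFG) == 2016

    def test_information_within_washout_blocks(self):
        got = classify_incident([pd.Timestamp("2013-01-15"), pd.Timestamp("2014-06-01")], CFG)
        assert got is None

    def test_old_information_outside_washout_allows(self):
        got = classify_incident([pd.Timestamp("2012-01-01"), pd.Timestamp("2015-05-01")], CFG)
        assert got == 2015

    def test_no_in_study_information_is_prevalent(self):
        assert classify_incident([pd.Timestamp("2010-05-01")], CFG) is None

    @given(st.lists(date_st, min_size=1, max_size=12))
    def test_agrees_with_bruteforce_scan(self, dates):
        dates = [pd.Timestamp(d) for d in dates]
        want = brute_incident_year(dates, CFG.study_start, CFG.study_end, CFG.washout_days, CFG.history_start)
        assert classify_incident(dates, CFG) == want


class TestFollowupEnd:
    def test_death_before_any_gap(self):
        end, reason = compute_followup_end(
            pd.Timestamp("2016-01-01"),
            [pd.Timestamp("2016-06-01"), pd.Timestamp("2017-06-01"), pd.Timestamp("2018-03-01")],
            pd.Timestamp("2018-04-02"),
            CFG,
        )
        assert (end, reason) == (pd.Timestamp("2018-04-02"), "death")

    def test_gap_censors_at_last_event_before_gap(self):
        end, reason = compute_followup_end(
            pd.Timestamp("2015-01-01"),
            [pd.Timestamp("2016-05-01"), pd.Timestamp("2018-09-01"), pd.Timestamp("2019-01-01")],
            None,
            CFG,
        )
        assert (end, reason) == (pd.Timestamp("2016-05-01"), "reimbursement_gap")

    def test_continuous_activity_runs_to_study_end(self):
        events = [pd.Timestamp(f"{y}-06-01") for y in range(2014, 2021)]
        end, reason = compute_followup_end(pd.Timestamp("2014-01-01"), events, None, CFG)
        assert (end, reason) == (pd.Timestamp("2020-12-31"), "study_end")

    def test_exact_730_day_silence_does_not_censor(self):
        events = [pd.Timestamp("2015-01-01"), pd.Timestamp("2015-01-01") + pd.Timedelta(days=730)]
        end, reason = compute_followup_end(pd.Timestamp("2015-01-01"), events, None, CFG)
        assert reason != "reimbursement_gap" or end > events[0]
        events2 = [pd.Timestamp("2015-01-01"), pd.Timestamp("2015-01-01") + pd.Timedelta(days=731)]
        end2, reason2 = compute_followup_end(pd.Timestamp("2015-01-01"), events2, None, CFG)
        assert (end2, reason2) == (pd.Timestamp("2015-01-01"), "reimbursement_gap")

    def test_trailing_silence_before_death_censors(self):
        """A death long after the last reimbursed event arrives after the
        member was already gap-censored."""
        end, reason = compute_followup_end(
            pd.Timestamp("2014-06-01"),
            [pd.Timestamp("2014-06-01"), pd.Timestamp("2015-02-01")],
            pd.Timestamp("2018-07-01"),
            CFG,
        )
        assert (end, reason) == (pd.Timestamp("2015-02-01"), "reimbursement_gap")

    @given(
        st.lists(date_st, min_size=0, max_size=10),
        st.lists(date_st, min_size=1, max_size=4),
        st.one_of(st.none(), date_st),
    )
    def test_adding_reimbursements_never_advances_the_end(self, base, extra, death):
        """Censoring monotonicity: more activity can only postpone the end."""
        start = pd.Timestamp("2014-01-01")
        death_ts = pd.Timestamp(death) if death else None
        end1, _ = compute_followup_end(start, [pd.Timestamp(d) for d in base], death_ts, CFG)
        end2, _ = compute_followup_end(start, [pd.Timestamp(d) for d in base + extra], death_ts, CFG)
        assert end2 >= end1

    @given(st.lists(date_st, min_size=0, max_size=10), st.one_of(st.none(), date_st))
    def test_end_never_precedes_start(self, dates, death):
        start = pd.Timestamp("2015-06-15")
        death_ts = pd.Timestamp(death) if death else None
        end, _ = compute_followup_end(start, [pd.Timestamp(d) for d in dates], death_ts, CFG)
        assert end >= start


def test_build_followup_classifies_prevalent_and_incident(codelists):
    ds = make_dataset(
        persons=[(1, "male", 1950), (2, "female", 1940)],
        stays=[(1, "2010-02-01", "C900", "PD"), (2, "2016-03-01", "C901", "PD")],
        disp=[
            (1, "2010-02-10", MM_DRUG),
            (1, "2013-05-01", MM_DRUG),  # inside the washout of the next one
            (1, "2014-05-01", MM_DRUG),
            (2, "2016-03-10", CHEMO),
        ],
        reimb=[(1, f"{y}-06-01") for y in range(2006, 2021)] + [(2, f"{y}-07-01") for y in range(2006, 2021)],
    )
    cohort = identify_mylord(ds, codelists=codelists)
    fu = build_followup(ds, cohort, codelists).set_index("person_id")
    # person 1: treated since 2010 → prevalent, index at study start
    assert fu.loc[1, "entry_status"] == "prevalent_at_2014"
    assert fu.loc[1, "index_date"] == pd.Timestamp("2014-01-01")
    assert fu.loc[1, "followup_start"] == pd.Timestamp("2014-01-01")
    # person 2: clean 2-year history → incident 2016, followed from first information
    assert fu.loc[2, "incident_year"] == 2016
    assert fu.loc[2, "followup_start"] == pd.Timestamp("2016-03-01")
    assert (fu["followup_start"] <= fu["followup_end"]).all()
    assert set(fu["end_reason"]) <= {"death", "study_end", "reimbursement_gap"}


def test_death_end_reason_matches_death_date(codelists):
    ds = make_dataset(
        persons=[(1, "male", 1950, "2018-04-02")],
        stays=[(1, "2015-02-01", "C900", "PD")],
        disp=[(1, "2015-02-10", MM_DRUG)],
        reimb=[(1, "2016-06-01"), (1, "2017-06-01"), (1, "2018-03-01")],
    )
    cohort = identify_mylord(ds, codelists=codelists)
    fu = build_followup(ds, cohort, codelists)
    assert fu.loc[0, "end_reason"] == "death"
    assert fu.loc[0, "followup_end"] == pd.Timestamp("2018-04-02")


def test_at_most_one_incident_year_per_member(big_sim, codelists):
    ds, _, _ = big_sim
    cohort = identify_mylord(ds, codelists=codelists)
    fu = build_followup(ds, cohort, codelists)
    assert fu["person_id"].is_unique
    assert fu["incident_year"].notna().sum() <= len(fu)
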