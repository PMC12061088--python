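import numpy as np
import pandas as pd
import pytest

from factories import ASCT, CHEMO, LEN, MM_DRUG, SPEP, THAL, UPEP, make_dataset
from mmepi.cohort import (
    AlgorithmConfig,
    identify_mylord,
    identify_palmaro,
    mm_hospital_dates,
    mm_treatment_dates,
    oral_imid_rule,
)
from oracles import all_person_events, brute_mylord, brute_palmaro


def _one(ds, pid=1):
    return (
        ds.stays[ds.stays["person_id"] == pid],
        ds.ltd_records[ds.ltd_records["person_id"] == pid],
        ds.dispensings[ds.dispensings["person_id"] == pid],
        ds.procedures[ds.procedures["person_id"] == pid],
    )


class TestHospitalDates:
    def test_sad_position_counts(self, codelists):
        ds = make_dataset(persons=[(1, "male", 1950)], stays=[(1, "2015-06-01", "C902", "SAD")])
        stays, *_ = _one(ds)
        assert mm_hospital_dates(stays, codelists, AlgorithmConfig.mylord()) == [pd.Timestamp("2015-06-01")]

    def test_non_mm_diagnosis_is_ignored(self, codelists):
        ds = make_dataset(persons=[(1, "male", 1950)], stays=[(1, "2015-06-01", "C81", "PD")])
        stays, *_ = _one(ds)
        assert mm_hospital_dates(stays, codelists, AlgorithmConfig.mylord()) == []

    def test_dates_sorted_ascending(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            stays=[(1, "2016-02-01", "C901", "RD"), (1, "2014-03-01", "C900", "PD")],
        )
        stays, *_ = _one(ds)
        assert mm_hospital_dates(stays, codelists, AlgorithmConfig.mylord()) == [
            pd.Timestamp("2014-03-01"),
            pd.Timestamp("2016-02-01"),
        ]


class TestTreatmentDates:
    def test_union_of_drug_and_asct(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            disp=[(1, "2015-01-10", MM_DRUG)],
            proc=[(1, "2015-04-01", ASCT)],
        )
        _, _, disp, proc = _one(ds)
        got = mm_treatment_dates(disp, proc, codelists, AlgorithmConfig.mylord())
        assert got == [pd.Timestamp("2015-01-10"), pd.Timestamp("2015-04-01")]

    def test_other_drugs_do_not_count(self, codelists):
        ds = make_dataset(persons=[(1, "male", 1950)], disp=[(1, "2015-01-10", "B01AC06")])
        _, _, disp, proc = _one(ds)
        assert mm_treatment_dates(disp, proc, codelists, AlgorithmConfig.mylord()) == []

    def test_window_clipping(self, codelists):
        cfg = AlgorithmConfig.mylord(identification_start="2014-01-01")
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            disp=[(1, "2015-01-10", CHEMO)],
            proc=[(1, "2013-04-01", ASCT)],
        )
        _, _, disp, proc = _one(ds)
        assert mm_treatment_dates(disp, proc, codelists, cfg) == [pd.Timestamp("2015-01-10")]


class TestOralRule:
    def run(self, ds, codelists, cfg=None):
        stays, _, disp, proc = _one(ds)
        return oral_imid_rule(disp, proc, stays, cfg or AlgorithmConfig.mylord(), codelists)

    def test_all_clauses_satisfied(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            disp=[(1, "2016-01-01", LEN), (1, "2016-03-01", LEN)],
            proc=[(1, "2016-01-31", SPEP), (1, "2016-04-01", UPEP)],
        )
        res = self.run(ds, codelists)
        assert res.qualifies and res.qualifying_date == pd.Timestamp("2016-01-01")
        assert res.drug == "lenalidomide"

    def test_dispensings_more_than_90_days_apart_fail(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            disp=[(1, "2016-01-01", LEN), (1, "2016-04-30", LEN)],  # 120 days
            proc=[(1, "2016-01-31", SPEP), (1, "2016-02-20", SPEP)],
        )
        assert not self.run(ds, codelists).qualifies

    def test_exclusion_diagnosis_anywhere_blocks(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            stays=[(1, "2008-06-01", "D461", "PD")],  # myelodysplastic syndrome, years earlier
            disp=[(1, "2016-01-01", LEN), (1, "2016-03-01", LEN)],
            proc=[(1, "2016-01-31", SPEP), (1, "2016-04-01", SPEP)],
        )
        assert not self.run(ds, codelists).qualifies

    def test_same_day_double_dispensing_does_not_count(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            disp=[(1, "2016-01-01", LEN), (1, "2016-01-01", LEN)],
            proc=[(1, "2016-01-31", SPEP), (1, "2016-02-20", SPEP)],
        )
        assert not self.run(ds, codelists).qualifies

    def test_monitoring_anchored_at_first_in_period_dispensing(self, codelists):
        # pair exists late, but the 120-day window counts from the first
        # in-period dispensing of the drug
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            disp=[(1, "2016-01-01", LEN), (1, "2016-10-01", LEN), (1, "2016-11-01", LEN)],
            proc=[(1, "2016-10-15", SPEP), (1, "2016-11-15", SPEP)],
        )
        assert not self.run(ds, codelists).qualifies


class TestIdentifyMylord:
    def test_stay_plus_treatment_included(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 1950)],
            stays=[(1, "2015-02-01", "C900", "PD")],
            disp=[(1, "2015-02-15", MM_DRUG)],
        )
        out = identify_mylord(ds, codelists=codelists)
        assert list(out["person_id"]) == [1]
        assert out.loc[0, "criterion"] == "hosp_or_ltd_treated"
        assert out.loc[0, "first_mm_information_date"] == pd.Timestamp("2015-02-01")
        assert out.loc[0, "first_mm_information_kind"] == "hospital_stay"

    def test_untreated_ltd_excluded(self, codelists):
        """LTD status alone is not enough: the treated-only restriction
        keeps smoldering myeloma out."""
        ds = make_dataset(persons=[(1, "male", 1950)], ltd=[(1, "2016-03-01", "C900")])
        assert len(identify_mylord(ds, codelists=codelists)) == 0

    def test_minor_excluded(self, codelists):
        ds = make_dataset(
            persons=[(1, "male", 2000)],
            stays=[(1, "2015-02-01", "C900", "PD")],
            disp=[(1, "2015-02-15", MM_DRUG)],
        )
        assert len(identify_mylord(ds, codelists=codelists)) == 0

    def test_stay_and_ltd_same_day_reported_as_combined_kind(self, codelists):
        ds = make_dataset(
            persons=[(1, "female", 1950)],
            stays=[(1, "2015-02-01", "C902", "RD")],
            ltd=[(1, "2015-02-01", "C900")],
            disp=[(1, "2015-03-15", CHEMO)],
        )
        out = identify_mylord(ds, codelists=codelists)
        assert out.loc[0, "first_mm_information_kind"] == "stay_and_ltd"

    def test_row_order_invariance(self, adversarial_sim, codelists):
        ds, _, _ = adversarial_sim
        base = identify_mylord(ds, codelists=codelists)
        shuffled = ds
        rng = np.random.default_rng(0)
        import dataclasses

        shuffled = dataclasses.replace(
            ds,
            stays=ds.stays.sample(frac=1, random_state=1).reset_index(drop=True),
            dispensings=ds.dispensings.sample(frac=1, random_state=2).reset_index(drop=True),
            procedures=ds.procedures.sample(frac=1, random_state=3).reset_index(drop=True),
            ltd_records=ds.ltd_records.sample(frac=1, random_state=4).reset_index(drop=True),
        )
        again = identify_mylord(shuffled, codelists=codelists)
        pd.testing.assert_frame_equal(base, again)

    def test_no_person_appears_twice(self, adversarial_sim, codelists):
        ds, _, _ = adversarial_sim
        out = identify_mylord(ds, codelists=codelists)
        assert out["person_id"].is_unique


class TestIdentifyPalmaro:
    def test_untreated_ltd_in_base_not_in_treated(self, codelists):
        ds = make_dataset(persons=[(1, "male", 1950)], ltd=[(1, "2016-03-01", "C900")])
        assert list(identify_palmaro(ds, "base", codelists=codelists)["person_id"]) == [1]
        assert len(identify_palmaro(ds, "treated_only", codelists=codelists)) == 0

    def test_oral_only_patient_invisible_to_palmaro_visible_to_mylord(self, codelists):
        """The motivating case: retail-pharmacy IMiD treatment with SPEP
        monitoring and no stay or LTD record."""
        ds = make_dataset(
            persons=[(1, "female", 1948)],
            disp=[(1, "2017-05-01", THAL), (1, "2017-06-15", THAL)],
            proc=[(1, "2017-05-20", SPEP), (1, "2017-08-01", UPEP)],
        )
        for variant in ("base", "from_2006", "treated_only"):
            assert len(identify_palmaro(ds, variant, codelists=codelists)) == 0
        out = identify_mylord(ds, codelists=codelists)
        assert list(out["person_id"]) == [1]
        assert out.loc[0, "criterion"] == "oral_imid_monitored"

    def test_unknown_variant_rejected(self, codelists):
        ds = make_dataset(persons=[(1, "male", 1950)])
        with pytest.raises(ValueError, match="variant"):
            identify_palmaro(ds, "bogus", codelists=codelists)

    def test_pre_2014_stay_needs_the_2006_variant(self, codelists):
        ds = make_dataset(persons=[(1, "male", 1950)], stays=[(1, "2013-06-01", "C900", "PD")])
        assert len(identify_palmaro(ds, "base", codelists=codelists)) == 0
        assert list(identify_palmaro(ds, "from_2006", codelists=codelists)["person_id"]) == [1]

    def test_treated_subset_of_base(self, small_sim, codelists):
        ds, _, _ = small_sim
        base = set(identify_palmaro(ds, "base", codelists=codelists)["person_id"])
        treated = set(identify_palmaro(ds, "treated_only", codelists=codelists)["person_id"])
        assert treated <= base


def test_palmaro_treated_subset_of_mylord(small_sim, codelists):
    ds, _, _ = small_sim
    my = set(identify_mylord(ds, codelists=codelists)["person_id"])
    pt = set(identify_palmaro(ds, "treated_only", codelists=codelists)["person_id"])
    assert pt <= my


def test_identification_matches_bruteforce_oracle_small(small_sim, codelists):
    """Person-by-person agreement with naive re-evaluation of the rules."""
    ds, _, _ = small_sim
    events = all_person_events(ds)
    by = ds.persons.set_index("person_id")["birth_year"]
    my_cfg = AlgorithmConfig.mylord()
    got = identify_mylord(ds, my_cfg, codelists).set_index("person_id")
    for pid, ev in events.items():
        inc, first = brute_mylord(ev, int(by[pid]), my_cfg, codelists)
        assert inc == (pid in got.index), f"person {pid}"
        if inc:
            assert got.loc[pid, "first_mm_information_date"] == first
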