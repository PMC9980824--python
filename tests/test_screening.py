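"""Candidate query, criterion windows, and greedy-vs-exhaustive equivalence."""
import pandas as pd
import pytest

from ecarm import screening
from ecarm.screening import (
    DEFAULT_CRITERIA,
    apply_criterion,
    induction_date,
    query_candidates,
    screen_greedy,
)
from conftest import ANCHOR, day, make_bundle, med_order, patient_row, uste_order

CRITERIA = {c.id: c for c in DEFAULT_CRITERIA}


def bundle_with(pid="P1", meds=None, dx_code="K50.10", surgeries=None, **patient_kw):
    meds = [uste_order(pid)] + (meds or [])
    return make_bundle(
        patients=[patient_row(pid, **patient_kw)],
        diagnoses=[{"id": pid, "code": dx_code, "date": day(-30)}],
        medications=meds,
        surgeries=surgeries,
    )


class TestQuery:
    def test_icd10_code_plus_order_included(self):
        b = bundle_with(dx_code="K50.10")
        assert query_candidates(b) == {"P1"}

    def test_icd9_code_plus_order_included(self):
        b = bundle_with(dx_code="555.1")
        assert query_candidates(b) == {"P1"}

    def test_nonmatching_prefix_excluded(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            diagnoses=[{"id": "P1", "code": "K51.9", "date": day(-30)}],
            medications=[uste_order("P1")],
        )
        assert query_candidates(b) == set()

    def test_code_without_order_excluded(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            diagnoses=[{"id": "P1", "code": "K50.10", "date": day(-30)}],
        )
        assert query_candidates(b) == set()


class TestInductionDate:
    def test_earliest_of_several_orders(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            medications=[uste_order("P1", start=pd.Timestamp("2019-03-05")),
                         uste_order("P1", start=pd.Timestamp("2019-01-05"))],
        )
        assert induction_date(b, "P1") == pd.Timestamp("2019-01-05")

    def test_duplicate_dates(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            medications=[uste_order("P1"), uste_order("P1")],
        )
        assert induction_date(b, "P1") == ANCHOR

    def test_no_order_is_error(self):
        b = make_bundle(patients=[patient_row("P1")])
        with pytest.raises(ValueError, match="not a candidate"):
            induction_date(b, "P1")


class TestCriteria:
    def test_iv_steroid_two_weeks_before_fails(self):
        b = bundle_with(meds=[med_order("P1", "iv_steroid", day(-14), day(-12))])
        res = apply_criterion(b, "P1", CRITERIA["excl-iv-steroid"], ANCHOR)
        assert res.verdict == "fail" and res.evidence

    def test_bare_patient_passes_all_exclusions(self):
        b = bundle_with()
        for spec in DEFAULT_CRITERIA:
            if spec.kind == "exclusion":
                assert apply_criterion(b, "P1", spec, ANCHOR).verdict == "pass"

    def test_immunomodulator_change_outside_12_weeks_passes(self):
        b = bundle_with(meds=[
            med_order("P1", "immunomodulator", day(-300), day(-91), dose=100),
            med_order("P1", "immunomodulator", day(-90), day(100), dose=150),
        ])
        spec = CRITERIA["excl-immunomodulator-change"]
        assert apply_criterion(b, "P1", spec, ANCHOR).verdict == "pass"  # 90 > 84

    def test_immunomodulator_change_inside_12_weeks_fails(self):
        b = bundle_with(meds=[
            med_order("P1", "immunomodulator", day(-300), day(-41), dose=100),
            med_order("P1", "immunomodulator", day(-40), day(100), dose=150),
        ])
        spec = CRITERIA["excl-immunomodulator-change"]
        assert apply_criterion(b, "P1", spec, ANCHOR).verdict == "fail"

    def test_stable_oral_steroid_passes_but_new_start_fails(self):
        stable = bundle_with(meds=[med_order("P1", "oral_steroid", day(-60), day(60),
                                             dose=40)])
        spec = CRITERIA["excl-oral-steroid-change"]
        assert apply_criterion(stable, "P1", spec, ANCHOR).verdict == "pass"
        fresh = bundle_with(meds=[med_order("P1", "oral_steroid", day(-10), day(60),
                                            dose=40)])
        assert apply_criterion(fresh, "P1", spec, ANCHOR).verdict == "fail"

    def test_stop_inside_window_counts_as_change(self):
        b = bundle_with(meds=[med_order("P1", "five_asa", day(-300), day(-15))])
        assert apply_criterion(b, "P1", CRITERIA["excl-5asa-change"], ANCHOR).verdict == "fail"

    def test_recent_vs_remote_bowel_surgery(self):
        recent = bundle_with(surgeries=[{"id": "P1", "procedure": "ileocecectomy",
                                         "date": day(-90)}])
        spec = CRITERIA["excl-recent-bowel-surgery"]
        assert apply_criterion(recent, "P1", spec, ANCHOR).verdict == "fail"
        remote = bundle_with(surgeries=[{"id": "P1", "procedure": "ileocecectomy",
                                         "date": day(-200)}])
        assert apply_criterion(remote, "P1", spec, ANCHOR).verdict == "pass"

    def test_major_surgery_ever_fails(self):
        b = bundle_with(surgeries=[{"id": "P1", "procedure": "major_resection",
                                    "date": day(-2000)}])
        spec = CRITERIA["excl-major-surgery-ever"]
        assert apply_criterion(b, "P1", spec, ANCHOR).verdict == "fail"

    def test_underage_fails_inclusion(self):
        b = bundle_with(birth=ANCHOR - pd.Timedelta(days=16 * 365))
        assert apply_criterion(b, "P1", CRITERIA["incl-age"], ANCHOR).verdict == "fail"

    def test_wrong_first_route_fails_dose_criterion(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            diagnoses=[{"id": "P1", "code": "K50.1", "date": day(-30)}],
            medications=[uste_order("P1", route="SC", dose=90.0)],
        )
        spec = CRITERIA["incl-uste-route-dose"]
        assert apply_criterion(b, "P1", spec, ANCHOR).verdict == "fail"

    def test_unknown_criterion_id(self):
        b = bundle_with()
        bad = screening.CriterionSpec("excl-nonsense", "exclusion", 21, "")
        with pytest.raises(KeyError):
            apply_criterion(b, "P1", bad, ANCHOR)


class TestGreedy:
    def test_all_pass_gives_flat_attrition(self):
        b = bundle_with()
        eligible, report, _ = screen_greedy(b, {"P1"})
        assert eligible == {"P1"}
        assert [n for _, n in report.stages] == [1] * (len(DEFAULT_CRITERIA) + 1)

    def test_double_failure_attributed_to_earlier_criterion(self):
        meds = [med_order("P1", "iv_steroid", day(-10), day(-8)),
                med_order("P1", "five_asa", day(-300), day(-15))]
        b = bundle_with(meds=meds)
        _, report, _ = screen_greedy(b, {"P1"})
        assert report.first_failures["excl-iv-steroid"] == 1
        assert report.first_failures["excl-5asa-change"] == 0

    def test_three_of_ten_fail_distinct_criteria(self):
        patients, dx, meds, surg = [], [], [], []
        for i in range(10):
            pid = f"P{i}"
            patients.append(patient_row(pid))
            dx.append({"id": pid, "code": "K50.10", "date": day(-30)})
            meds.append(uste_order(pid))
        meds.append(med_order("P0", "iv_steroid", day(-5), day(-3)))
        surg.append({"id": "P1", "procedure": "ileocecectomy", "date": day(-90)})
        surg.append({"id": "P2", "procedure": "major_resection", "date": day(-900)})
        b = make_bundle(patients=patients, diagnoses=dx, medications=meds,
                        surgeries=surg)
        eligible, report, _ = screen_greedy(b, {f"P{i}" for i in range(10)})
        assert len(eligible) == 7
        hits = {k: v for k, v in report.first_failures.items() if v}
        assert hits == {"excl-iv-steroid": 1, "excl-recent-bowel-surgery": 1,
                        "excl-major-surgery-ever": 1}

    def test_matches_exhaustive_evaluation(self, small_bundle):
        """The greedy short-circuit never changes the final eligible set."""
        bundle, _ = small_bundle
        candidates = query_candidates(bundle)
        eligible, report, _ = screen_greedy(bundle, candidates)
        anchors = screening.induction_dates(bundle, sorted(candidates))
        exhaustive = {
            pid for pid in candidates
            if all(apply_criterion(bundle, pid, spec, anchors[pid]).verdict == "pass"
                   for spec in DEFAULT_CRITERIA)
        }
        assert eligible == exhaustive
        report.validate()

    def test_attrition_counts_sum(self, small_bundle):
        bundle, _ = small_bundle
        candidates = query_candidates(bundle)
        eligible, report, _ = screen_greedy(bundle, candidates)
        assert len(candidates) - sum(report.first_failures.values()) == len(eligible)
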