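"""Informatics element ascertainment and concordance statistics."""
import numpy as np
import pandas as pd
import pytest

from ecarm import ascertainment, temporal
from ecarm.ascertainment import (
    concordance_binary,
    concordance_continuous,
    concordance_total,
)
from conftest import day, make_bundle, med_order, patient_row, uste_order


class TestAscertainNonPro3:
    def test_quiet_patient_all_flags_false(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            medications=[uste_order("P1")],
            labs=[{"id": "P1", "analyte": "hematocrit", "value": 42.0, "unit": "%",
                   "date": day(-3)}],
        )
        comp = ascertainment.ascertain_nonpro3(b, "P1", temporal.baseline_window(12))
        assert comp.eim_count == 0.0
        assert comp.antidiarrheal_use == 0.0
        assert comp.abdominal_mass == 0.0
        assert comp.hematocrit == 42.0  # female at reference: zero deficit term

    def test_uveitis_code_in_window_sets_flag(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            diagnoses=[{"id": "P1", "code": "H20.9", "date": day(-20)}],
            medications=[uste_order("P1")],
        )
        comp = ascertainment.ascertain_nonpro3(b, "P1", temporal.baseline_window(12))
        assert comp.eim_count == 1.0

    def test_code_outside_window_ignored(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            diagnoses=[{"id": "P1", "code": "H20.9", "date": day(-200)}],
            medications=[uste_order("P1")],
        )
        comp = ascertainment.ascertain_nonpro3(b, "P1", temporal.baseline_window(12))
        assert comp.eim_count == 0.0

    def test_antidiarrheal_order_spanning_window(self):
        b = make_bundle(
            patients=[patient_row("P1")],
            medications=[uste_order("P1"),
                         med_order("P1", "antidiarrheal_opiate", day(-100), day(50))],
        )
        comp = ascertainment.ascertain_nonpro3(b, "P1", temporal.baseline_window(12))
        assert comp.antidiarrheal_use == 1.0

    def test_missing_labs_propagate(self):
        b = make_bundle(patients=[patient_row("P1")], medications=[uste_order("P1")])
        comp = ascertainment.ascertain_nonpro3(b, "P1", temporal.baseline_window(12))
        assert comp.hematocrit is None and comp.weight is None


class TestConcordanceBinary:
    def test_identical_vectors(self):
        flags = pd.DataFrame({"fever": [0, 1] * 22 + [0]})  # 45 patients
        assert concordance_binary(flags, flags.copy())["fever"] == 1.0

    def test_41_of_45_agree(self):
        inf = pd.DataFrame({"arthritis": [0] * 45})
        man = pd.DataFrame({"arthritis": [0] * 41 + [1] * 4})
        assert concordance_binary(inf, man)["arthritis"] == pytest.approx(41 / 45)

    def test_single_disagreeing_pair(self):
        inf = pd.DataFrame({"fever": [1]})
        man = pd.DataFrame({"fever": [0]})
        assert concordance_binary(inf, man)["fever"] == 0.0

    def test_missing_pairs_dropped(self):
        inf = pd.DataFrame({"fever": [1, np.nan, 0, 1]})
        man = pd.DataFrame({"fever": [1, 1, np.nan, 0]})
        assert concordance_binary(inf, man)["fever"] == 0.5

    def test_zero_comparable_pairs_raise(self):
        inf = pd.DataFrame({"fever": [np.nan, np.nan]})
        man = pd.DataFrame({"fever": [1.0, 0.0]})
        with pytest.raises(ValueError, match="zero comparable"):
            concordance_binary(inf, man)


class TestConcordanceContinuous:
    def test_hand_arithmetic(self):
        inf = pd.DataFrame({"hematocrit": [40.0, 38.0]})
        man = pd.DataFrame({"hematocrit": [41.0, 38.0]})
        res = concordance_continuous(inf, man).loc["hematocrit"]
        assert res["mae"] == pytest.approx(0.5)
        assert res["n_pairs"] == 2

    def test_identical_vectors_zero_mae(self):
        v = pd.DataFrame({"weight": [60.0, 70.0, 80.0]})
        assert concordance_continuous(v, v.copy()).loc["weight", "mae"] == 0.0

    def test_all_missing_side_flags_undefined_mae(self):
        inf = pd.DataFrame({"hematocrit": [np.nan, np.nan]})
        man = pd.DataFrame({"hematocrit": [40.0, 42.0]})
        res = concordance_continuous(inf, man).loc["hematocrit"]
        assert np.isnan(res["mae"])
        assert res["missing_informatics"] == 1.0
        assert res["missing_manual"] == 0.0


class TestConcordanceTotal:
    def test_perfect_agreement(self):
        x = pd.Series([100.0, 200.0, 300.0, 400.0])
        res = concordance_total(x, x.copy())
        assert res["r2"] == pytest.approx(1.0)
        assert res["mae"] == 0.0

    def test_pearson_hand_case(self):
        x = pd.Series([1.0, 2.0, 3.0])
        y = pd.Series([1.0, 2.0, 4.0])
        res = concordance_total(x, y)
        assert res["r2"] == pytest.approx(0.9643, abs=1e-3)

    def test_affine_rescaling_leaves_r2_unchanged(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(300, 50, 30))
        y = x + rng.normal(0, 10, 30)
        base = concordance_total(x, y)["r2"]
        scaled = concordance_total(2.5 * x - 40.0, y)["r2"]
        assert scaled == pytest.approx(base)

    def test_constant_vector_rejected(self):
        x = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            concordance_total(x, pd.Series([5.0, 5.0, 5.0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            concordance_total(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))

    def test_remission_denominators_per_method(self):
        inf = pd.Series([100.0, 160.0, 300.0, np.nan])
        man = pd.Series([120.0, 140.0, 310.0, 90.0])
        res = concordance_total(inf, man)
        assert res["remission_informatics"] == 1
        assert res["denominator_informatics"] == 3
        assert res["remission_manual"] == 3
        assert res["denominator_manual"] == 4


class TestMatrixScores:
    def test_matrix_and_componentwise_paths_agree(self, small_bundle):
        bundle, _ = small_bundle
        from ecarm import screening
        eligible, _, _ = screening.screen_greedy(bundle,
                                                 screening.query_candidates(bundle))
        ids = sorted(eligible)[:10]
        windows = {"baseline": temporal.baseline_window(12),
                   "week12": temporal.WEEK12_WINDOW,
                   "week24": temporal.WEEK24_WINDOW}
        matrix = ascertainment.build_cohort_matrix(bundle, ids, windows)
        complete = matrix.values.dropna()
        if len(complete):
            scores = ascertainment.cdai_scores(complete, "baseline")
            assert (scores >= 0).all()

    def test_imputed_values_clipped_into_scale(self):
        row = pd.Series({
            "pain__baseline": 5.2, "diarrhea__baseline": -0.4,
            "wellbeing__baseline": 1.0, "hematocrit__baseline": 41.0,
            "weight__baseline": 60.0, "antidiarrheal__baseline": 0.2,
            "steroid__baseline": 0.0, "sex": "female", "standard_weight": 60.0,
            **{f"{c}__baseline": 0.0 for c in ascertainment.EIM_CATEGORIES},
        })
        comp = ascertainment.components_from_row(row, "baseline")
        assert comp.abdominal_pain_7d == 21.0  # daily pain capped at 3
        assert comp.liquid_stools_7d == 0.0
        assert comp.antidiarrheal_use == 0.0
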