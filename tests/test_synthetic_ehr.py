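"""Generator contracts: determinism, emission consistency, masking, calibration."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from ecarm import screening, temporal
from ecarm.synthetic_ehr import (
    GeneratorConfig,
    calibrate_baseline_location,
    generate_bundle,
    mask_mcar,
    true_mean_decline,
    truth_matrix,
)
from conftest import perfect_config


def test_zero_patients_gives_empty_bundle_and_truth():
    bundle, truth = generate_bundle(GeneratorConfig(n_patients=0, seed=1))
    assert all(len(df) == 0 for df in bundle.tables().values())
    assert len(truth.per_patient) == 0 and len(truth.anchors) == 0


def test_same_seed_byte_identical(tmp_path):
    cfg = GeneratorConfig(n_patients=30, seed=9)
    for d in ("a", "b"):
        bundle, truth = generate_bundle(dataclasses.replace(cfg))
        bundle.write(tmp_path / d)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_bundle_roundtrip(tmp_path):
    bundle, _ = generate_bundle(GeneratorConfig(n_patients=15, seed=3))
    bundle.write(tmp_path)
    back = type(bundle).read(tmp_path)
    assert set(back.patients["id"]) == set(bundle.patients["id"])
    assert len(back.medications) == len(bundle.medications)
    back.validate()


def test_full_documentation_leaves_no_missing_pro():
    """With documentation probability 1, daily visits and no induction delay,
    every assessment window of every patient contains all three PRO elements."""
    bundle, _ = generate_bundle(perfect_config(n_patients=25, seed=2))
    ids = list(bundle.patients["id"])
    for window in (temporal.baseline_window(12), temporal.WEEK12_WINDOW,
                   temporal.WEEK24_WINDOW):
        snap = temporal.snapshot_table(bundle, ids, window)
        assert not snap[["abdominal_pain", "diarrhea", "wellbeing"]].isna().any().any()


def test_emission_consistency_with_zero_noise():
    """Noise-free pre-induction observations equal the baseline ground truth."""
    bundle, truth = generate_bundle(perfect_config(n_patients=10, seed=4))
    anchors = truth.anchors
    base = anchors[anchors["period"] == "baseline"].set_index("id")
    pro = bundle.pro_observations
    ind = screening.induction_dates(bundle)
    off = (pro["date"].to_numpy() - ind.reindex(pro["id"]).to_numpy()).astype(
        "timedelta64[D]"
    ).astype(int)
    pre = pro[off <= 0]
    expected = {"abdominal_pain": "pain_daily", "diarrhea": "diarrhea_daily",
                "wellbeing": "wellbeing_daily"}
    for element, col in expected.items():
        obs = pre[pre["element"] == element]
        truth_vals = base.loc[obs["id"], col].to_numpy()
        assert (obs["value"].to_numpy(dtype=float) == truth_vals).all()


def test_missingness_monotone_in_documentation_prob():
    def missing_fraction(prob):
        cfg = GeneratorConfig(n_patients=80, seed=11, pro_documentation_prob=prob,
                              ineligible_fraction_per_criterion={})
        bundle, _ = generate_bundle(cfg)
        snap = temporal.snapshot_table(
            bundle, list(bundle.patients["id"]), temporal.baseline_window(12)
        )
        return snap["abdominal_pain"].isna().mean()

    assert missing_fraction(0.9) <= missing_fraction(0.5) <= missing_fraction(0.2)


def test_induction_delay_depresses_availability_near_week0():
    """Authorization delays produce the characteristic rise of availability
    with lookback: few patients have a PRO within 2 weeks of induction, most
    have one within 12."""
    cfg = GeneratorConfig(n_patients=150, seed=13,
                          ineligible_fraction_per_criterion={})
    bundle, _ = generate_bundle(cfg)
    curve = temporal.availability_curve(bundle, set(bundle.patients["id"]), 16)
    assert (curve.fractions.loc[2] < curve.fractions.loc[12]).all()


def test_latent_trajectory_nonnegative_and_anchored(small_bundle):
    bundle, truth = small_bundle
    cfg = truth.config
    days = np.arange(-150, 211)
    for pid in list(truth.per_patient.index)[:10]:
        latent = truth.latent_cdai(pid, days)
        assert (latent >= 0).all()
        pre = latent[days <= 0]
        assert np.allclose(pre, pre[0])  # flat before induction
    assert true_mean_decline(cfg, 84.0) == pytest.approx(cfg.effect_week12)
    assert true_mean_decline(cfg, 168.0) == pytest.approx(cfg.effect_week24)
    assert true_mean_decline(cfg, -5.0) == 0.0


def test_calibrated_location_hits_truncated_mean():
    loc = calibrate_baseline_location(305.0, scale=120.0)
    a, b = (220.0 - loc) / 120.0, (450.0 - loc) / 120.0
    assert truncnorm.mean(a, b, loc=loc, scale=120.0) == pytest.approx(305.0, abs=1e-6)


@pytest.mark.parametrize(
    "overrides",
    [dict(n_patients=-1), dict(responder_fraction=1.5),
     dict(pro_documentation_prob=-0.1), dict(baseline_cdai_scale=0.0),
     dict(effect_week12=100.0, effect_week24=250.0),  # ratio outside (1, 2)
     dict(effect_week12=0.0, effect_week24=50.0),
     dict(ineligible_fraction_per_criterion={"not-a-criterion": 0.1})],
)
def test_invalid_configs_rejected(overrides):
    with pytest.raises(ValueError):
        generate_bundle(GeneratorConfig(**overrides))


class TestMaskMcar:
    def test_zero_prob_is_identity(self, small_bundle):
        full = truth_matrix(small_bundle[1])
        masked = mask_mcar(full, 0.0, seed=1)
        pd.testing.assert_frame_equal(masked.values, full.values)
        assert masked.mask.all().all()

    def test_prob_one_masks_everything(self, small_bundle):
        full = truth_matrix(small_bundle[1])
        masked = mask_mcar(full, 1.0, seed=1)
        assert not masked.mask.any().any()

    def test_masked_fraction_matches_binomial(self, small_bundle):
        full = truth_matrix(small_bundle[1])
        masked = mask_mcar(full, 0.3, seed=2)
        n = full.mask.to_numpy().sum()
        frac = 1.0 - masked.mask.to_numpy().sum() / n
        assert abs(frac - 0.3) < 2 * np.sqrt(0.3 * 0.7 / n)

    def test_observed_values_untouched(self, small_bundle):
        full = truth_matrix(small_bundle[1])
        masked = mask_mcar(full, 0.4, seed=3)
        still = masked.mask
        for c in full.values.columns:
            pd.testing.assert_series_equal(
                masked.values.loc[still[c], c], full.values.loc[still[c], c]
            )
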