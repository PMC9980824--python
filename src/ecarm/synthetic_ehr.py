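"""Synthetic EHR generator with known ground truth.

No public accession exists for the real cohort, so every downstream stage is
exercised against simulated bundles that emulate the statistical structure of
standard-of-care EHR data for Crohn's disease patients starting ustekinumab:

* irregular clinic visits (renewal process with exponential gaps) and an
  authorization-delay documentation gap immediately before the first infusion;
* a latent CDAI trajectory per patient — a truncated-normal-calibrated
  baseline minus, for responders, a saturating decline anchored to the
  configured mean week-12/week-24 effects;
* lossy emission: the three patient-reported elements are documented together
  at a visit or not at all; labs are documented less often than symptoms;
* rare persistent extraintestinal-manifestation codes (class imbalance);
* steroid users tapering off after induction;
* per-criterion ineligibility injections with known flags;
* a manual-abstraction view whose completeness dominates the structured view.

The generator's defaults are the study conditions: cohort-mean declines of 95
and 133 CDAI points at weeks 12 and 24, an eligible-range baseline mean of
305, 59% female, 38% baseline steroid use, and per-criterion ineligibility
tuned so roughly a quarter of candidates survive screening.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import cdai
from .bundle import EhrBundle, PERIODS
from .imputation import CohortMatrix
from .screening import CRITERION_IDS
from .temporal import WEEK12_WINDOW, WEEK24_WINDOW, baseline_window

#: CDAI points per unit of daily PRO value (weight x 7-day expansion)
_PAIN_PTS = 35.0  # 5 * 7
_WELLBEING_PTS = 49.0  # 7 * 7
_STOOL_PTS = 14.0  # 2 * 7

_EIM_CODES = {
    "fever": "R50.9",
    "arthritis": "M13.0",
    "uveitis": "H20.9",
    "anal": "K60.2",
    "skin_oral": "L52",
    "other_fistula": "K63.2",
}
EIM_CATEGORIES = tuple(_EIM_CODES)

_STD_WEIGHT = {"male": 70.0, "female": 60.0}

_WINDOWS = {
    "baseline": baseline_window(12),
    "week12": WEEK12_WINDOW,
    "week24": WEEK24_WINDOW,
}


def calibrate_baseline_location(
    target_mean: float = 305.0,
    scale: float = 120.0,
    lo: float = 220.0,
    hi: float = 450.0,
) -> float:
    """Normal location whose [lo, hi]-truncated mean equals ``target_mean``.

    Solved analytically via the truncated-normal mean expression (root find
    on the location), so the expected baseline CDAI of the in-range cohort
    matches the target by construction.
    """
    if not lo < target_mean < hi:
        raise ValueError("target_mean must lie inside (lo, hi)")

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return float(truncnorm.mean(a, b, loc=loc, scale=scale))

    return float(
        brentq(lambda L: trunc_mean(L) - target_mean, lo - 8 * scale, hi + 8 * scale,
               xtol=1e-8)
    )


@dataclass
class GeneratorConfig:
    """Generative knobs; defaults encode the emulated study conditions."""

    n_patients: int = 736
    seed: int = 0
    #: location of the (untruncated) baseline CDAI normal; None = solve so the
    #: in-range (220-450) mean equals eligible_cdai_mean
    baseline_cdai_location: float | None = None
    baseline_cdai_scale: float = 120.0
    eligible_cdai_mean: float = 305.0
    #: cohort-mean CDAI declines among all treated patients (responders decline
    #: by effect/responder_fraction, non-responders by 0)
    effect_week12: float = 95.0
    effect_week24: float = 133.0
    responder_fraction: float = 0.8
    visit_interval_mean: float = 30.0  # days
    induction_delay_mean: float = 30.0  # days
    pro_documentation_prob: float = 0.75  # per visit, all three elements jointly
    lab_documentation_prob: float = 0.4  # per visit
    eim_prevalence: float = 0.03  # per category
    steroid_baseline_prob: float = 0.38
    steroid_taper_prob_per_week: float = 0.10
    antidiarrheal_prob: float = 0.20
    female_prob: float = 0.59
    age_mean: float = 34.0
    age_sd: float = 14.0
    symptom_noise_sd: float = 10.0  # CDAI points, at emission
    hct_noise_sd: float = 0.5  # percent points
    weight_noise_sd: float = 0.4  # kg
    crp_log_sd: float = 0.9  # lognormal sigma around median 12.3 mg/L
    abstraction_recovery_prob: float = 0.5
    ineligible_fraction_per_criterion: dict[str, float] = field(
        default_factory=lambda: {c: 0.131 for c in CRITERION_IDS}
    )
    span_lo_day: int = -150
    span_hi_day: int = 210

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        probs = {
            "responder_fraction": self.responder_fraction,
            "pro_documentation_prob": self.pro_documentation_prob,
            "lab_documentation_prob": self.lab_documentation_prob,
            "eim_prevalence": self.eim_prevalence,
            "steroid_baseline_prob": self.steroid_baseline_prob,
            "steroid_taper_prob_per_week": self.steroid_taper_prob_per_week,
            "antidiarrheal_prob": self.antidiarrheal_prob,
            "female_prob": self.female_prob,
            "abstraction_recovery_prob": self.abstraction_recovery_prob,
            **{f"ineligible[{k}]": v
               for k, v in self.ineligible_fraction_per_criterion.items()},
        }
        for name, p in probs.items():
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        for name, s in (("baseline_cdai_scale", self.baseline_cdai_scale),
                        ("visit_interval_mean", self.visit_interval_mean),
                        ("age_sd", self.age_sd)):
            if not (np.isfinite(s) and s > 0):
                raise ValueError(f"{name} must be positive")
        for name, v in (("induction_delay_mean", self.induction_delay_mean),
                        ("symptom_noise_sd", self.symptom_noise_sd),
                        ("hct_noise_sd", self.hct_noise_sd),
                        ("weight_noise_sd", self.weight_noise_sd)):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative")
        if self.effect_week12 < 0 or self.effect_week24 < 0:
            raise ValueError("effects must be non-negative")
        if self.effect_week12 > 0:
            ratio = self.effect_week24 / self.effect_week12
            if not 1.0 < ratio < 2.0:
                raise ValueError(
                    "the saturating decline requires effect_week24/effect_week12 in (1, 2)"
                )
        elif self.effect_week24 > 0:
            raise ValueError("effect_week24 > 0 requires effect_week12 > 0")
        unknown = set(self.ineligible_fraction_per_criterion) - set(CRITERION_IDS)
        if unknown:
            raise ValueError(f"unknown criterion ids: {sorted(unknown)}")

    def resolved_location(self) -> float:
        if self.baseline_cdai_location is not None:
            return float(self.baseline_cdai_location)
        return calibrate_baseline_location(
            self.eligible_cdai_mean, self.baseline_cdai_scale
        )

    def trajectory_params(self) -> tuple[float, float]:
        """(asymptote, tau) of the cohort-mean decline A*(1 - exp(-t/tau))."""
        e12, e24 = self.effect_week12, self.effect_week24
        if e12 == 0:
            return 0.0, 1.0
        x = e24 / e12 - 1.0  # exp(-84/tau)
        return e12 / (1.0 - x), -84.0 / math.log(x)


def true_mean_decline(config: GeneratorConfig, day: float) -> float:
    """Configured cohort-mean CDAI decline at ``day`` days post induction."""
    if day <= 0:
        return 0.0
    a, tau = config.trajectory_params()
    return a * (1.0 - math.exp(-day / tau))


def _decompose(total_pro_points: float, shares: np.ndarray) -> tuple[int, int, int]:
    """Split PRO points into (pain, stools, wellbeing) daily ordinals.

    Pain and wellbeing are capped at their scale maxima with the excess spilt
    into the unbounded stool count, so the realised point total tracks the
    latent one up to ordinal rounding.
    """
    t = max(total_pro_points, 0.0)
    pain_pts = min(shares[0] * t, 3 * _PAIN_PTS)
    wb_pts = min(shares[1] * t, 4 * _WELLBEING_PTS)
    stool_pts = max(t - pain_pts - wb_pts, 0.0)
    pain_d = int(np.clip(round(pain_pts / _PAIN_PTS), 0, 3))
    wb_d = int(np.clip(round(wb_pts / _WELLBEING_PTS), 0, 4))
    stool_d = int(max(round(stool_pts / _STOOL_PTS), 0))
    return pain_d, stool_d, wb_d


@dataclass
class GroundTruth:
    """Latent truth behind a generated bundle (enables parameter recovery)."""

    per_patient: pd.DataFrame  # indexed by id
    anchors: pd.DataFrame  # (id, period, components, cdai)
    config: GeneratorConfig

    def latent_cdai(self, patient: str, days) -> np.ndarray:
        """Dense latent CDAI over arbitrary day offsets from induction."""
        row = self.per_patient.loc[patient]
        a, tau = self.config.trajectory_params()
        days = np.asarray(days, dtype=float)
        decline = np.where(
            days > 0,
            (a / max(self.config.responder_fraction, 1e-12)) * (1 - np.exp(-days / tau)),
            0.0,
        )
        t = np.maximum(row["pro_points_baseline"] - row["responder"] * decline, 0.0)
        return np.maximum(t + row["nonpro_points"], 0.0)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_patient.to_csv(directory / "truth_patients.csv")
        self.anchors.to_csv(directory / "truth_anchors.csv", index=False)
        cfg = dataclasses.asdict(self.config)
        (directory / "manifest.json").write_text(
            json.dumps({"config": cfg, "seed": self.config.seed}, indent=2, sort_keys=True)
        )


def _patient_truth(cfg: GeneratorConfig, rng: np.random.Generator, loc: float) -> dict:
    p: dict = {}
    p["sex"] = "female" if rng.random() < cfg.female_prob else "male"
    p["age"] = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18.5, 85.0))
    p["standard_weight"] = _STD_WEIGHT[p["sex"]] + rng.normal(0.0, 5.0)
    p["weight"] = p["standard_weight"] * (1.0 + rng.normal(-0.02, 0.04))
    p["disease_duration"] = float(np.clip(rng.normal(10.0, 11.0), 0.3, 40.0))
    p["prior_biologic"] = int(rng.random() < 0.89)
    p["montreal"] = rng.choice(["L1", "L3", "L2", "other"], p=[0.13, 0.52, 0.30, 0.05])
    p["hct"] = float(
        np.clip(cdai.HCT_REFERENCE[p["sex"]] - rng.normal(2.0, 2.0), 25.0, 55.0)
    )
    p["crp"] = float(12.3 * math.exp(rng.normal(0.0, cfg.crp_log_sd)))
    for cat in EIM_CATEGORIES:
        p[f"eim_{cat}"] = int(rng.random() < cfg.eim_prevalence)
    p["antidiarrheal"] = int(rng.random() < cfg.antidiarrheal_prob)
    p["steroid_user"] = int(rng.random() < cfg.steroid_baseline_prob)
    p["steroid_taper_weeks"] = (
        int(rng.geometric(max(cfg.steroid_taper_prob_per_week, 1e-9)))
        if p["steroid_user"] else 0
    )
    p["responder"] = int(rng.random() < cfg.responder_fraction)
    p["baseline_cdai"] = float(max(rng.normal(loc, cfg.baseline_cdai_scale), 30.0))
    shares = rng.dirichlet([9.0, 15.0, 26.0])  # (pain, wellbeing, stools)
    p["share_pain"], p["share_wellbeing"], p["share_stools"] = map(float, shares)
    p["induction_delay"] = float(rng.exponential(cfg.induction_delay_mean))
    for crit in CRITERION_IDS:
        frac = cfg.ineligible_fraction_per_criterion.get(crit, 0.0)
        p[f"injected__{crit}"] = int(rng.random() < frac)
    if p["injected__incl-age"]:
        p["age"] = float(rng.uniform(12.0, 17.5))
    # non-PRO CDAI point contribution (abdominal mass not reliably coded: 0)
    eim_count = sum(p[f"eim_{c}"] for c in EIM_CATEGORIES)
    p["nonpro_points"] = (
        20.0 * eim_count
        + 30.0 * p["antidiarrheal"]
        + 6.0 * (cdai.HCT_REFERENCE[p["sex"]] - p["hct"])
        + 100.0 * (1.0 - p["weight"] / p["standard_weight"])
    )
    p["pro_points_baseline"] = max(p["baseline_cdai"] - p["nonpro_points"], 0.0)
    return p


def _visit_days(cfg: GeneratorConfig, rng: np.random.Generator, delay: float) -> list[int]:
    days, t = [], float(cfg.span_lo_day)
    while True:
        t += rng.exponential(cfg.visit_interval_mean)
        if t > cfg.span_hi_day:
            break
        if -delay < t < 0:  # authorization gap before the first infusion
            continue
        days.append(int(round(t)))
    return sorted(set(days))


def generate_bundle(config: GeneratorConfig) -> tuple[EhrBundle, GroundTruth]:
    """Generate a bundle and its ground truth; deterministic given the config."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    loc = cfg.resolved_location()
    a_cohort, tau = cfg.trajectory_params()
    r = max(cfg.responder_fraction, 1e-12)

    patients_rows, dx_rows, med_rows, lab_rows, vit_rows = [], [], [], [], []
    pro_rows, surg_rows, abs_rows, truth_rows, anchor_rows = [], [], [], [], []

    base_date = pd.Timestamp("2013-01-01")

    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        p = _patient_truth(cfg, rng, loc)
        t0 = base_date + pd.Timedelta(days=int(rng.integers(0, 2500)))

        def date(day: int | float) -> pd.Timestamp:
            return t0 + pd.Timedelta(days=int(round(day)))

        def latent_pro(day: float) -> float:
            decline = (a_cohort / r) * (1 - math.exp(-day / tau)) if day > 0 else 0.0
            return max(p["pro_points_baseline"] - p["responder"] * decline, 0.0)

        shares = np.array([p["share_pain"], p["share_wellbeing"], p["share_stools"]])
        birth = t0 - pd.Timedelta(days=int(round(p["age"] * 365.25)))
        patients_rows.append(
            (pid, birth, p["sex"], round(p["standard_weight"], 1),
             round(p["disease_duration"], 1), p["prior_biologic"], p["montreal"])
        )

        # --- diagnoses -----------------------------------------------------
        if not p["injected__incl-cd-dx"]:
            dx_rows.append((pid, "K50.10", date(-30)))
            if rng.random() < 0.3:
                dx_rows.append((pid, "555.1", date(-60)))
        else:
            dx_rows.append((pid, "K51.9", date(-30)))  # mimic, fails the CD query

        # --- medications ---------------------------------------------------
        steroid_intervals: list[tuple[float, float]] = []
        if p["injected__incl-uste-route-dose"]:
            med_rows.append((pid, "ustekinumab", "ustekinumab", 90.0, "SC", date(0), date(0)))
        else:
            med_rows.append((pid, "ustekinumab", "ustekinumab", 390.0, "IV", date(0), date(0)))
        for d in (56, 112, 168):
            if d <= cfg.span_hi_day:
                med_rows.append((pid, "ustekinumab", "ustekinumab", 90.0, "SC",
                                 date(d), date(d)))
        if p["steroid_user"]:
            start = -float(rng.uniform(40.0, 150.0))
            end = 7.0 * p["steroid_taper_weeks"] - 4.0
            med_rows.append((pid, "prednisone", "oral_steroid", 40.0, "PO",
                             date(start), date(max(end, start + 1))))
            steroid_intervals.append((start, max(end, start + 1)))
        if p["injected__excl-iv-steroid"]:
            med_rows.append((pid, "methylprednisolone", "iv_steroid", 60.0, "IV",
                             date(-10), date(-8)))
            steroid_intervals.append((-10.0, -8.0))
        if p["injected__excl-oral-steroid-change"]:
            med_rows.append((pid, "prednisone", "oral_steroid", 40.0, "PO",
                             date(-50), date(-20)))
            med_rows.append((pid, "prednisone", "oral_steroid", 20.0, "PO",
                             date(-14), date(30)))
            steroid_intervals += [(-50.0, -20.0), (-14.0, 30.0)]
        if p["injected__excl-immunomodulator-change"]:
            med_rows.append((pid, "azathioprine", "immunomodulator", 100.0, "PO",
                             date(-250), date(-41)))
            med_rows.append((pid, "azathioprine", "immunomodulator", 150.0, "PO",
                             date(-40), date(120)))
        elif rng.random() < 0.3:  # stable immunomodulator background
            med_rows.append((pid, "azathioprine", "immunomodulator", 100.0, "PO",
                             date(-300), date(cfg.span_hi_day)))
        if p["injected__excl-cd-antibiotic-change"]:
            med_rows.append((pid, "ciprofloxacin", "antibiotic_cd", 500.0, "PO",
                             date(-10), date(4)))
        if p["injected__excl-5asa-change"]:
            med_rows.append((pid, "mesalamine", "five_asa", 2400.0, "PO",
                             date(-300), date(-15)))
        elif rng.random() < 0.2:
            med_rows.append((pid, "mesalamine", "five_asa", 2400.0, "PO",
                             date(-400), date(cfg.span_hi_day)))
        if p["antidiarrheal"]:
            med_rows.append((pid, "loperamide", "antidiarrheal_opiate", 2.0, "PO",
                             date(-100), date(cfg.span_hi_day)))

        # --- surgeries -----------------------------------------------------
        if p["injected__excl-recent-bowel-surgery"]:
            surg_rows.append((pid, "ileocecectomy", date(-90)))
        if p["injected__excl-major-surgery-ever"]:
            surg_rows.append((pid, "major_resection", date(-800)))
        if rng.random() < 0.1:
            surg_rows.append((pid, "other", date(-400)))

        # --- visits and lossy emission ------------------------------------
        visits = _visit_days(cfg, rng, p["induction_delay"])
        documented, lab_days = [], []
        for d in visits:
            for cat in EIM_CATEGORIES:
                if p[f"eim_{cat}"]:
                    dx_rows.append((pid, _EIM_CODES[cat], date(d)))
            if rng.random() < cfg.pro_documentation_prob:
                documented.append(d)
                t_obs = latent_pro(d) + rng.normal(0.0, cfg.symptom_noise_sd)
                pain_d, stool_d, wb_d = _decompose(t_obs, shares)
                pro_rows.append((pid, "abdominal_pain", pain_d, date(d)))
                pro_rows.append((pid, "diarrhea", stool_d, date(d)))
                pro_rows.append((pid, "wellbeing", wb_d, date(d)))
            if rng.random() < cfg.lab_documentation_prob:
                lab_days.append(d)
                lab_rows.append((pid, "hematocrit",
                                 round(p["hct"] + rng.normal(0.0, cfg.hct_noise_sd), 1),
                                 "%", date(d)))
                lab_rows.append((pid, "crp",
                                 round(max(p["crp"] * math.exp(rng.normal(0.0, 0.15)),
                                           0.1), 1),
                                 "mg/L", date(d)))
                vit_rows.append((pid, round(p["weight"]
                                            + rng.normal(0.0, cfg.weight_noise_sd), 1),
                                 date(d)))

        # --- anchored truth and manual-abstraction view -------------------
        def steroid_in(lo: float, hi: float) -> int:
            return int(any(s <= hi and e >= lo for s, e in steroid_intervals))

        for period, win in _WINDOWS.items():
            pain_d, stool_d, wb_d = _decompose(latent_pro(win.anchor_day), shares)
            eim_count = sum(p[f"eim_{c}"] for c in EIM_CATEGORIES)
            comp = cdai.CdaiComponents(
                liquid_stools_7d=7.0 * stool_d,
                abdominal_pain_7d=7.0 * pain_d,
                wellbeing_7d=7.0 * wb_d,
                eim_count=float(eim_count),
                antidiarrheal_use=float(p["antidiarrheal"]),
                abdominal_mass=0.0,
                hematocrit=p["hct"],
                sex=p["sex"],
                weight=p["weight"],
                standard_weight=p["standard_weight"],
            )
            steroid = steroid_in(win.lo_day, win.hi_day)
            anchor_rows.append(
                (pid, period, pain_d, stool_d, wb_d, eim_count, p["antidiarrheal"],
                 steroid, p["hct"], p["weight"], p["crp"], cdai.compute_cdai(comp))
            )
            pro_present = any(win.lo_day <= d <= win.hi_day for d in documented)
            lab_present = any(win.lo_day <= d <= win.hi_day for d in lab_days)
            if pro_present or rng.random() < cfg.abstraction_recovery_prob:
                abs_rows.append((pid, "abdominal_pain", pain_d, period))
                abs_rows.append((pid, "diarrhea", stool_d, period))
                abs_rows.append((pid, "wellbeing", wb_d, period))
            for cat in EIM_CATEGORIES:
                abs_rows.append((pid, cat, p[f"eim_{cat}"], period))
            abs_rows.append((pid, "antidiarrheal", p["antidiarrheal"], period))
            abs_rows.append((pid, "steroid", steroid, period))
            if lab_present or rng.random() < cfg.abstraction_recovery_prob:
                abs_rows.append((pid, "hematocrit", round(p["hct"], 1), period))
                abs_rows.append((pid, "weight", round(p["weight"], 1), period))

        p["induction_date"] = t0
        p["id"] = pid
        truth_rows.append(p)

    bundle = EhrBundle()
    if cfg.n_patients:
        bundle.patients = pd.DataFrame(
            patients_rows,
            columns=["id", "birth_date", "sex", "standard_weight",
                     "disease_duration", "prior_biologic", "montreal"],
        )
        bundle.diagnoses = pd.DataFrame(dx_rows, columns=["id", "code", "date"])
        bundle.medications = pd.DataFrame(
            med_rows,
            columns=["id", "drug_name", "drug_class", "dose", "route",
                     "start_date", "end_date"],
        )
        bundle.labs = pd.DataFrame(lab_rows, columns=["id", "analyte", "value",
                                                      "unit", "date"])
        bundle.vitals = pd.DataFrame(vit_rows, columns=["id", "weight", "date"])
        bundle.pro_observations = pd.DataFrame(
            pro_rows, columns=["id", "element", "value", "date"]
        )
        if surg_rows:
            bundle.surgeries = pd.DataFrame(surg_rows,
                                            columns=["id", "procedure", "date"])
        bundle.abstraction = pd.DataFrame(abs_rows,
                                          columns=["id", "element", "value", "period"])

    per_patient = pd.DataFrame(truth_rows).set_index("id") if truth_rows else pd.DataFrame()
    anchors = pd.DataFrame(
        anchor_rows,
        columns=["id", "period", "pain_daily", "diarrhea_daily", "wellbeing_daily",
                 "eim_count", "antidiarrheal", "steroid", "hematocrit", "weight",
                 "crp", "cdai"],
    )
    return bundle, GroundTruth(per_patient, anchors, cfg)


def truth_matrix(truth: GroundTruth) -> CohortMatrix:
    """Fully-observed cohort matrix built directly from ground truth.

    Mirrors the column layout of the informatics-built matrix, which makes it
    the natural complete reference for masking experiments.
    """
    per, anchors = truth.per_patient, truth.anchors
    ids = list(per.index)
    blocks, col_types = [], {}
    rename = {"pain_daily": "pain", "diarrhea_daily": "diarrhea",
              "wellbeing_daily": "wellbeing"}
    for period in PERIODS:
        sub = anchors[anchors["period"] == period].set_index("id").reindex(ids)
        block = pd.DataFrame(index=sub.index)
        for col in ("pain_daily", "diarrhea_daily", "wellbeing_daily",
                    "hematocrit", "crp", "weight"):
            name = f"{rename.get(col, col)}__{period}"
            block[name] = sub[col].astype(float)
            col_types[name] = "continuous"
        for cat in EIM_CATEGORIES:
            name = f"{cat}__{period}"
            block[name] = per[f"eim_{cat}"].astype(float)
            col_types[name] = "categorical"
        for col in ("antidiarrheal", "steroid"):
            name = f"{col}__{period}"
            block[name] = sub[col].astype(float)
            col_types[name] = "categorical"
        blocks.append(block)
    static = pd.DataFrame(index=per.index)
    static["age"] = per["age"].astype(float)
    static["sex"] = per["sex"]
    static["standard_weight"] = per["standard_weight"].astype(float)
    static["disease_duration"] = per["disease_duration"].astype(float)
    static["prior_biologic"] = per["prior_biologic"].astype(float)
    static["montreal"] = per["montreal"]
    col_types.update({"age": "continuous", "sex": "categorical",
                      "standard_weight": "continuous",
                      "disease_duration": "continuous",
                      "prior_biologic": "categorical", "montreal": "categorical"})
    values = pd.concat(blocks + [static], axis=1)
    values.index.name = "id"
    return CohortMatrix(values, col_types)


def mask_mcar(matrix: CohortMatrix, missing_prob: float, seed: int = 0) -> CohortMatrix:
    """Mask each observed cell independently with ``missing_prob`` (MCAR).

    The caller keeps the input matrix as the reference for error measurement.
    """
    if not 0.0 <= missing_prob <= 1.0:
        raise ValueError("missing_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    mask = matrix.mask.copy()
    for c in values.columns:
        drop = mask[c].to_numpy() & (rng.random(len(values)) < missing_prob)
        mask[c] = mask[c] & ~drop
        values.loc[drop, c] = np.nan
    return CohortMatrix(values, dict(matrix.col_types), mask)
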