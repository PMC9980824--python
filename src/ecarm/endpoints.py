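"""Study endpoints: CDAI reduction, remission and steroid-use proportions,
and cohort characterization.

Numeric endpoints are summarised as mean +/- SE (sample SD / sqrt(n));
binary endpoints as count / denominator with the percent rounded to the
nearest integer, half away from zero.  Steroid-free remission requires both
a CDAI at or below the remission threshold and no oral/IV steroid order
intersecting the assessment window.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cdai
from .bundle import EhrBundle
from .screening import induction_dates
from .temporal import WindowSpec


def steroid_flag(bundle: EhrBundle, patient: str, window: WindowSpec) -> bool:
    """True iff any oral/IV steroid order's [start, end] intersects the window."""
    return bool(steroid_flags(bundle, [patient], window).loc[patient])


def steroid_flags(bundle: EhrBundle, ids, window: WindowSpec) -> pd.Series:
    ids = sorted(ids)
    anchors = induction_dates(bundle, ids)
    out = pd.Series(False, index=pd.Index(ids, name="id"))
    meds = bundle.medications
    meds = meds[meds["id"].isin(ids) & meds["drug_class"].isin(["oral_steroid", "iv_steroid"])]
    if len(meds):
        anchor = anchors.reindex(meds["id"]).to_numpy()
        s = (meds["start_date"].to_numpy() - anchor).astype("timedelta64[D]").astype(int)
        e = (meds["end_date"].to_numpy() - anchor).astype("timedelta64[D]").astype(int)
        hit = (s <= window.hi_day) & (e >= window.lo_day)
        out.loc[out.index.isin(meds.loc[hit, "id"].unique())] = True
    return out


def mean_reduction(baseline, follow_up) -> tuple[float, float]:
    """Mean and SE of per-patient reduction (baseline - follow-up).

    SE = sample SD (n-1 denominator) / sqrt(n); n = 1 returns SE 0 with a
    warning (degenerate sample).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(follow_up, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must be paired and equal length")
    if b.size == 0:
        raise ValueError("empty score vectors")
    if np.isnan(b).any() or np.isnan(f).any():
        raise ValueError("scores must be complete (impute first)")
    red = b - f
    if red.size == 1:
        warnings.warn("single patient: SE reported as 0 by convention")
        return float(red[0]), 0.0
    return float(red.mean()), float(red.std(ddof=1) / math.sqrt(red.size))


def proportion(indicators) -> tuple[int, int, int]:
    """(count, denominator, percent); percent rounds half away from zero."""
    arr = np.asarray(list(indicators))
    if arr.size == 0:
        raise ValueError("empty indicator vector")
    count = int(arr.astype(bool).sum())
    denom = int(arr.size)
    percent = int(math.floor(100.0 * count / denom + 0.5))
    return count, denom, percent


def steroid_free_remission(
    scores, steroid, thresholds: cdai.CdaiThresholds = cdai.DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Indicator: remission (score <= threshold) AND not on steroids."""
    s = np.asarray(scores, dtype=float)
    st = np.asarray(steroid, dtype=bool)
    if s.shape != st.shape:
        raise ValueError("scores and steroid flags must be aligned")
    return (s <= thresholds.remission) & ~st


@dataclass
class EndpointSummary:
    n: int
    reduction_week12: tuple[float, float]  # (mean, SE)
    reduction_week24: tuple[float, float]
    remission_week12: tuple[int, int, int]  # (count, denom, percent)
    remission_week24: tuple[int, int, int]
    steroid_free_remission_week12: tuple[int, int, int]
    steroid_free_remission_week24: tuple[int, int, int]
    steroid_use_baseline: tuple[int, int, int]
    steroid_use_week12: tuple[int, int, int]
    steroid_use_week24: tuple[int, int, int]

    def to_dict(self) -> dict:
        def prop(t):
            return {"count": t[0], "denominator": t[1], "percent": t[2]}

        return {
            "n": self.n,
            "reduction_week12": {"mean": self.reduction_week12[0], "se": self.reduction_week12[1]},
            "reduction_week24": {"mean": self.reduction_week24[0], "se": self.reduction_week24[1]},
            "remission_week12": prop(self.remission_week12),
            "remission_week24": prop(self.remission_week24),
            "steroid_free_remission_week12": prop(self.steroid_free_remission_week12),
            "steroid_free_remission_week24": prop(self.steroid_free_remission_week24),
            "steroid_use_baseline": prop(self.steroid_use_baseline),
            "steroid_use_week12": prop(self.steroid_use_week12),
            "steroid_use_week24": prop(self.steroid_use_week24),
        }


def summarize_endpoints(
    scores: pd.DataFrame,
    steroid: pd.DataFrame,
    thresholds: cdai.CdaiThresholds = cdai.DEFAULT_THRESHOLDS,
) -> EndpointSummary:
    """Endpoint summary from per-patient scores and steroid flags.

    ``scores`` and ``steroid`` have one row per cohort member and columns
    baseline / week12 / week24 (scores complete post-imputation).
    """
    steroid = steroid.reindex(scores.index)
    out = {"n": int(len(scores))}
    for period in ("week12", "week24"):
        out[f"reduction_{period}"] = mean_reduction(scores["baseline"], scores[period])
        out[f"remission_{period}"] = proportion(
            scores[period] <= thresholds.remission
        )
        sfr = steroid_free_remission(
            scores[period].to_numpy(), steroid[period].to_numpy(), thresholds
        )
        out[f"steroid_free_remission_{period}"] = proportion(sfr)
    for period in ("baseline", "week12", "week24"):
        out[f"steroid_use_{period}"] = proportion(steroid[period])
    return EndpointSummary(**out)


def characterize_cohort(
    bundle: EhrBundle, cohort, baseline_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Cohort characterization table: demographics, disease history, baseline
    CDAI (mean +/- SD), median CRP, and baseline steroid use.

    ``baseline_matrix`` is the completed cohort-matrix value frame (one row
    per patient) restricted or restrictable to the cohort.
    """
    ids = sorted(cohort)
    if not ids:
        raise ValueError("empty cohort")
    m = baseline_matrix.loc[ids]
    from .ascertainment import cdai_scores

    scores = cdai_scores(m, "baseline")
    rows = []

    def mean_sd(label, series):
        s = pd.to_numeric(series, errors="coerce").dropna()
        sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
        rows.append({"field": label, "statistic": "mean±sd",
                     "value": float(s.mean()), "spread": sd})

    def pct(label, indicator):
        arr = np.asarray(indicator, dtype=float)
        c, d, p = proportion(arr > 0.5)
        rows.append({"field": label, "statistic": "percent", "value": p,
                     "spread": np.nan})

    mean_sd("Age in years", m["age"])
    pct("Female Gender", (m["sex"] == "female"))
    if "disease_duration" in m.columns:
        mean_sd("Disease Duration", m["disease_duration"])
    if "crp__baseline" in m.columns:
        crp = pd.to_numeric(m["crp__baseline"], errors="coerce").dropna()
        rows.append({"field": "C-Reactive Protein", "statistic": "median",
                     "value": float(crp.median()) if len(crp) else np.nan,
                     "spread": np.nan})
    if "prior_biologic" in m.columns:
        pct("History of Biologic Intolerance or Refractoriness",
            pd.to_numeric(m["prior_biologic"], errors="coerce").fillna(0))
    if "montreal" in m.columns:
        for label, code in (("Ileal (L1)", "L1"), ("Ileocolonic (L3)", "L3"),
                            ("Colonic (L2)", "L2"), ("Other", "other")):
            pct(f"Disease Location: {label}", (m["montreal"] == code))
    mean_sd("Baseline CDAI", scores)
    if "steroid__baseline" in m.columns:
        pct("Baseline steroid use",
            pd.to_numeric(m["steroid__baseline"], errors="coerce").fillna(0))
    return pd.DataFrame(rows, columns=["field", "statistic", "value", "spread"])
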