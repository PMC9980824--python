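"""Candidate query and trial-adapted eligibility screening with attrition reporting.

Phase 1 identifies candidates by a code/order query (at least one Crohn's
disease diagnosis code, ICD-9 555* or ICD-10 K50*, plus at least one
ustekinumab order).  Phase 2 applies the trial-adapted eligibility criteria.
All lookback windows are anchored at the induction date (day of the first
ustekinumab order) using the half-open convention (anchor - lookback, anchor]:
the anchor day itself counts as prior exposure for non-ustekinumab orders,
because the time of day of the first infusion is unknowable.

Screening is greedy — a patient is eliminated at the first disqualifying
criterion in a fixed order — which determines how exclusions are *attributed*
but not the final eligible set.  Biologic-washout criteria are deliberately
absent (the emulation dropped them after finding they removed nearly all
real-world candidates).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import EhrBundle

#: diagnosis-code prefixes identifying Crohn's disease (ICD-9 / ICD-10 dialects)
CD_CODE_PREFIXES = ("555", "K50")

#: week/month lookbacks in unambiguous day units
DAYS_3_WEEKS = 21
DAYS_12_WEEKS = 84
DAYS_6_MONTHS = 183

#: maintenance ustekinumab subcutaneous dose (mg)
USTE_SC_DOSE = 90.0


@dataclass(frozen=True)
class CriterionSpec:
    id: str
    kind: str  # "inclusion" | "exclusion"
    lookback_days: float  # math.inf means "ever"
    description: str

    def __post_init__(self) -> None:
        if self.kind not in ("inclusion", "exclusion"):
            raise ValueError("kind must be inclusion or exclusion")
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")


#: criteria in the order they are printed in the emulated protocol; the
#: baseline-CDAI range criterion is intentionally absent here (applied after
#: imputation, when a complete baseline CDAI exists).
DEFAULT_CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("incl-age", "inclusion", math.inf, "age >= 18 at induction"),
    CriterionSpec("incl-cd-dx", "inclusion", math.inf, "Crohn's disease diagnosis code present"),
    CriterionSpec(
        "incl-uste-route-dose", "inclusion", math.inf,
        "ustekinumab at approved route/dose (first order IV, later SC 90 mg)",
    ),
    CriterionSpec("excl-iv-steroid", "exclusion", DAYS_3_WEEKS, "IV steroids within 3 weeks"),
    CriterionSpec(
        "excl-oral-steroid-change", "exclusion", DAYS_3_WEEKS,
        "oral corticosteroid dose change within 3 weeks",
    ),
    CriterionSpec(
        "excl-immunomodulator-change", "exclusion", DAYS_12_WEEKS,
        "methotrexate/6-MP/azathioprine dose change within 12 weeks",
    ),
    CriterionSpec(
        "excl-cd-antibiotic-change", "exclusion", DAYS_3_WEEKS,
        "Crohn's-indicated antibiotic dose change within 3 weeks",
    ),
    CriterionSpec(
        "excl-5asa-change", "exclusion", DAYS_3_WEEKS, "5-ASA dose change within 3 weeks",
    ),
    CriterionSpec(
        "excl-recent-bowel-surgery", "exclusion", DAYS_6_MONTHS,
        "segmental colectomy or ileocecectomy within 6 months",
    ),
    CriterionSpec(
        "excl-major-surgery-ever", "exclusion", math.inf, "history of major bowel surgery",
    ),
)

CRITERION_IDS = tuple(c.id for c in DEFAULT_CRITERIA)

_DOSE_CHANGE_CLASS = {
    "excl-oral-steroid-change": "oral_steroid",
    "excl-immunomodulator-change": "immunomodulator",
    "excl-cd-antibiotic-change": "antibiotic_cd",
    "excl-5asa-change": "five_asa",
}


@dataclass
class ScreenResult:
    patient: str
    criterion: str
    verdict: str  # "pass" | "fail"
    evidence: list[tuple] = field(default_factory=list)  # (table, row ref, date)


@dataclass
class AttritionReport:
    """Sequential exclusion counts: (stage label, n remaining) plus
    per-criterion first-failure counts."""

    stages: list[tuple[str, int]]
    first_failures: dict[str, int]

    def validate(self) -> None:
        counts = [n for _, n in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("attrition counts must be non-increasing")
        if counts and counts[0] - sum(self.first_failures.values()) != counts[-1]:
            raise ValueError("first-failure counts do not sum to attrition")

    def to_dict(self) -> dict:
        return {"stages": self.stages, "first_failures": self.first_failures}


def query_candidates(bundle: EhrBundle) -> set[str]:
    """Candidate ids: >=1 Crohn's code (555*/K50*) AND >=1 ustekinumab order."""
    dx = bundle.diagnoses
    codes = dx["code"].astype(str)
    has_cd = set(dx.loc[codes.str.startswith(CD_CODE_PREFIXES), "id"])
    meds = bundle.medications
    has_uste = set(meds.loc[meds["drug_class"] == "ustekinumab", "id"])
    return has_cd & has_uste


def induction_date(bundle: EhrBundle, patient: str) -> pd.Timestamp:
    """Earliest ustekinumab order start date — day 0 for every window."""
    meds = bundle.medications
    mask = (meds["id"] == patient) & (meds["drug_class"] == "ustekinumab")
    if not mask.any():
        raise ValueError(f"{patient}: no ustekinumab order; not a candidate")
    return meds.loc[mask, "start_date"].min()


def induction_dates(bundle: EhrBundle, patients=None) -> pd.Series:
    """Vectorised :func:`induction_date` over many patients."""
    meds = bundle.medications
    uste = meds[meds["drug_class"] == "ustekinumab"]
    dates = uste.groupby("id")["start_date"].min()
    if patients is not None:
        dates = dates.reindex(list(patients))
        if dates.isna().any():
            missing = dates.index[dates.isna()].tolist()
            raise ValueError(f"no ustekinumab order for {missing[:5]}")
    return dates


class _PatientView:
    """Pre-extracted per-patient arrays with day offsets from the anchor."""

    __slots__ = ("patient", "anchor", "birth", "codes", "meds", "surg")

    def __init__(self, bundle: EhrBundle, patient: str, anchor: pd.Timestamp):
        self.patient = patient
        self.anchor = anchor
        row = bundle.patients.loc[bundle.patients["id"] == patient]
        self.birth = row["birth_date"].iloc[0] if len(row) else pd.NaT
        dx = bundle.diagnoses
        sel = dx["id"] == patient
        self.codes = dx.loc[sel, ["code", "date"]].reset_index()
        meds = bundle.medications
        sel = meds["id"] == patient
        self.meds = meds.loc[sel].reset_index()
        surg = bundle.surgeries
        sel = surg["id"] == patient
        self.surg = surg.loc[sel, ["procedure", "date"]].reset_index()

    def _off(self, dates) -> np.ndarray:
        d = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
        if d.empty:
            return np.empty(0, dtype=int)
        return (d - self.anchor).dt.days.to_numpy()


def _in_window(offsets: np.ndarray, lookback: float) -> np.ndarray:
    """Half-open window (anchor - lookback, anchor] in day offsets."""
    return (offsets > -lookback) & (offsets <= 0)


def _eval_criterion(view: _PatientView, spec: CriterionSpec) -> ScreenResult:
    pid, anchor = view.patient, view.anchor
    evidence: list[tuple] = []

    if spec.id == "incl-age":
        age = (anchor - view.birth).days / 365.25
        ok = age >= 18
        evidence = [("patients", pid, view.birth)]
    elif spec.id == "incl-cd-dx":
        codes = view.codes["code"].astype(str)
        hit = codes.str.startswith(CD_CODE_PREFIXES)
        ok = bool(hit.any())
        evidence = [
            ("diagnoses", int(i), d)
            for i, d in zip(view.codes.loc[hit, "index"], view.codes.loc[hit, "date"])
        ]
    elif spec.id == "incl-uste-route-dose":
        uste = view.meds[view.meds["drug_class"] == "ustekinumab"].sort_values("start_date")
        if not len(uste):
            ok = False
        else:
            first_ok = uste["route"].iloc[0] == "IV"
            later = uste.iloc[1:]
            later_ok = bool(
                ((later["route"] == "SC") & (later["dose"] == USTE_SC_DOSE)).all()
            )
            ok = first_ok and later_ok
            bad = uste if not ok else uste.iloc[:0]
            evidence = [
                ("medications", int(i), d)
                for i, d in zip(bad["index"], bad["start_date"])
            ]
    elif spec.id == "excl-iv-steroid":
        iv = view.meds[view.meds["drug_class"] == "iv_steroid"]
        starts = view._off(iv["start_date"])
        ends = view._off(iv["end_date"])
        # receipt: exposure interval intersects the lookback window
        hit = (starts <= 0) & (ends > -spec.lookback_days)
        ok = not hit.any()
        evidence = [
            ("medications", int(i), d)
            for i, d, h in zip(iv["index"], iv["start_date"], hit) if h
        ]
    elif spec.id in _DOSE_CHANGE_CLASS:
        ok, evidence = _dose_change(view, _DOSE_CHANGE_CLASS[spec.id], spec.lookback_days)
        ok = not ok
    elif spec.id == "excl-recent-bowel-surgery":
        sel = view.surg["procedure"].isin(["segmental_colectomy", "ileocecectomy"])
        offs = view._off(view.surg["date"])
        hit = sel.to_numpy() & _in_window(offs, spec.lookback_days)
        ok = not hit.any()
        evidence = [
            ("surgeries", int(i), d)
            for i, d, h in zip(view.surg["index"], view.surg["date"], hit) if h
        ]
    elif spec.id == "excl-major-surgery-ever":
        sel = view.surg["procedure"] == "major_resection"
        offs = view._off(view.surg["date"])
        hit = sel.to_numpy() & (offs <= 0)
        ok = not hit.any()
        evidence = [
            ("surgeries", int(i), d)
            for i, d, h in zip(view.surg["index"], view.surg["date"], hit) if h
        ]
    else:
        raise KeyError(f"unknown criterion id: {spec.id}")

    return ScreenResult(pid, spec.id, "pass" if ok else "fail", evidence)


def _dose_change(view: _PatientView, drug_class: str, lookback: float):
    """A dose change = two orders of the class with different doses whose later
    start falls in the window, or any start/stop of the class inside it."""
    orders = view.meds[view.meds["drug_class"] == drug_class].sort_values("start_date")
    if not len(orders):
        return False, []
    starts = view._off(orders["start_date"])
    ends = view._off(orders["end_date"])
    hit = _in_window(starts, lookback)  # new start inside window
    stop = _in_window(ends, lookback)  # stop inside window
    doses = orders["dose"].to_numpy(dtype=float)
    pair = np.zeros(len(orders), dtype=bool)
    for j in range(1, len(orders)):
        if _in_window(starts[j : j + 1], lookback)[0] and (doses[:j] != doses[j]).any():
            pair[j] = True
    flag = hit | stop | pair
    evidence = [
        ("medications", int(i), d)
        for i, d, h in zip(orders["index"], orders["start_date"], flag) if h
    ]
    return bool(flag.any()), evidence


def apply_criterion(
    bundle: EhrBundle, patient: str, spec: CriterionSpec, anchor: pd.Timestamp
) -> ScreenResult:
    """Evaluate one eligibility criterion for one patient at the given anchor."""
    return _eval_criterion(_PatientView(bundle, patient, anchor), spec)


def _views(bundle: EhrBundle, patients: list[str], anchors: pd.Series):
    """Build per-patient views in one grouped pass over each table."""
    pat = bundle.patients.set_index("id")["birth_date"]
    dx_groups = dict(iter(bundle.diagnoses.groupby("id")))
    med_groups = dict(iter(bundle.medications.groupby("id")))
    surg_groups = dict(iter(bundle.surgeries.groupby("id")))
    empty_dx = bundle.diagnoses.iloc[:0]
    empty_med = bundle.medications.iloc[:0]
    empty_surg = bundle.surgeries.iloc[:0]
    for pid in patients:
        v = _PatientView.__new__(_PatientView)
        v.patient = pid
        v.anchor = anchors[pid]
        v.birth = pat.get(pid, pd.NaT)
        v.codes = dx_groups.get(pid, empty_dx)[["code", "date"]].reset_index()
        v.meds = med_groups.get(pid, empty_med).reset_index()
        v.surg = surg_groups.get(pid, empty_surg)[["procedure", "date"]].reset_index()
        yield v


def screen_greedy(
    bundle: EhrBundle,
    candidates,
    specs: tuple[CriterionSpec, ...] = DEFAULT_CRITERIA,
) -> tuple[set[str], AttritionReport, list[ScreenResult]]:
    """Greedy sequential screening: stop each patient at the first failure.

    Returns the eligible set, the attrition report, and the per-patient
    :class:`ScreenResult` records actually evaluated.  The eligible set is
    order-invariant; only the attribution of exclusions depends on spec order.
    """
    ordered = sorted(candidates)
    anchors = induction_dates(bundle, ordered)
    eligible: set[str] = set()
    first_failures = {s.id: 0 for s in specs}
    results: list[ScreenResult] = []
    for view in _views(bundle, ordered, anchors):
        failed = None
        for spec in specs:
            res = _eval_criterion(view, spec)
            results.append(res)
            if res.verdict == "fail":
                failed = spec.id
                break
        if failed is None:
            eligible.add(view.patient)
        else:
            first_failures[failed] += 1
    stages = [("candidates", len(ordered))]
    remaining = len(ordered)
    for spec in specs:
        remaining -= first_failures[spec.id]
        stages.append((spec.id, remaining))
    report = AttritionReport(stages, first_failures)
    report.validate()
    return eligible, report, results


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    rows = [
        {
            "patient": r.patient,
            "criterion": r.criterion,
            "verdict": r.verdict,
            "n_evidence": len(r.evidence),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["patient", "criterion", "verdict", "n_evidence"])
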