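"""Crohn's Disease Activity Index (CDAI): composite score, remission, eligibility.

The CDAI is a weighted sum of eight components (Best's formula): 7-day liquid
stool count, 7-day abdominal-pain sum (daily 0-3), 7-day general-wellbeing sum
(daily 0-4), number of extraintestinal complication categories (0-6),
antidiarrheal/opiate use, abdominal mass on exam, hematocrit deficit relative
to a sex-specific reference (47% men / 42% women), and percent deviation from
standard body weight.  Remission is a score <= 150; the emulated trial's
eligibility band is 220-450 inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

#: sex-specific hematocrit reference (percent) used in the hematocrit term
HCT_REFERENCE = {"male": 47.0, "female": 42.0}

#: Best-formula multipliers, keyed by component
WEIGHTS = {
    "liquid_stools_7d": 2.0,
    "abdominal_pain_7d": 5.0,
    "wellbeing_7d": 7.0,
    "eim_count": 20.0,
    "antidiarrheal_use": 30.0,
    "abdominal_mass": 10.0,
    "hct_deficit": 6.0,
    "weight_deviation": 100.0,
}


class MissingComponentError(ValueError):
    """Raised when a CDAI component is missing; complete via imputation first."""


@dataclass(frozen=True)
class CdaiThresholds:
    """Score cut-points: trial eligibility band and remission ceiling."""

    eligibility_lo: float = 220.0
    eligibility_hi: float = 450.0
    remission: float = 150.0

    def __post_init__(self) -> None:
        if not (self.remission < self.eligibility_lo < self.eligibility_hi):
            raise ValueError("thresholds must satisfy remission < lo < hi")


DEFAULT_THRESHOLDS = CdaiThresholds()


@dataclass
class CdaiComponents:
    """The eight CDAI elements at one timepoint; any field may be None (missing).

    ``liquid_stools_7d``, ``abdominal_pain_7d`` and ``wellbeing_7d`` are 7-day
    sums.  Single-visit daily assessments are converted upstream by the x7
    convention (see :func:`from_daily`).
    """

    liquid_stools_7d: Optional[float] = None
    abdominal_pain_7d: Optional[float] = None
    wellbeing_7d: Optional[float] = None
    eim_count: Optional[float] = None
    antidiarrheal_use: Optional[float] = None
    abdominal_mass: Optional[float] = None
    hematocrit: Optional[float] = None
    sex: Optional[str] = None
    weight: Optional[float] = None
    standard_weight: Optional[float] = None

    def missing_fields(self) -> list[str]:
        return [f.name for f in fields(self) if getattr(self, f.name) is None]


def from_daily(
    stools_per_day: float,
    pain_daily: float,
    wellbeing_daily: float,
    **kwargs,
) -> CdaiComponents:
    """Build components from single-visit daily PRO values via the x7 convention."""
    return CdaiComponents(
        liquid_stools_7d=7.0 * stools_per_day,
        abdominal_pain_7d=7.0 * pain_daily,
        wellbeing_7d=7.0 * wellbeing_daily,
        **kwargs,
    )


def _validate(c: CdaiComponents) -> None:
    missing = c.missing_fields()
    if missing:
        raise MissingComponentError(
            f"missing CDAI components {missing}; complete the matrix by "
            "imputation before scoring"
        )
    if c.liquid_stools_7d < 0 or c.abdominal_pain_7d < 0 or c.wellbeing_7d < 0:
        raise ValueError("PRO sums must be non-negative")
    if not 0 <= c.eim_count <= 6:
        raise ValueError("eim_count must be in [0, 6]")
    if not 0 < c.hematocrit < 100:
        raise ValueError("hematocrit must be in (0, 100) percent")
    if c.sex not in HCT_REFERENCE:
        raise ValueError(f"sex must be one of {sorted(HCT_REFERENCE)}")
    if c.weight <= 0 or c.standard_weight <= 0:
        raise ValueError("weights must be positive")


def compute_cdai(components: CdaiComponents) -> float:
    """Best-formula CDAI from a complete set of components.

    The hematocrit and weight terms may individually be negative (values
    better than reference); the total is floored at 0.  Raises
    :class:`MissingComponentError` if any component is missing.
    """
    c = components
    _validate(c)
    hct_deficit = HCT_REFERENCE[c.sex] - c.hematocrit
    weight_deviation = 1.0 - c.weight / c.standard_weight
    score = (
        WEIGHTS["liquid_stools_7d"] * c.liquid_stools_7d
        + WEIGHTS["abdominal_pain_7d"] * c.abdominal_pain_7d
        + WEIGHTS["wellbeing_7d"] * c.wellbeing_7d
        + WEIGHTS["eim_count"] * c.eim_count
        + WEIGHTS["antidiarrheal_use"] * c.antidiarrheal_use
        + WEIGHTS["abdominal_mass"] * c.abdominal_mass
        + WEIGHTS["hct_deficit"] * hct_deficit
        + WEIGHTS["weight_deviation"] * weight_deviation
    )
    return max(score, 0.0)


def classify_remission(score: float, thresholds: CdaiThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Clinical remission: score <= remission threshold (boundary inclusive)."""
    return score <= thresholds.remission


def check_cdai_eligibility(score: float, thresholds: CdaiThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Trial eligibility: lo <= score <= hi, both boundaries inclusive."""
    return thresholds.eligibility_lo <= score <= thresholds.eligibility_hi
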