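"""Assessment-window machinery: empirical baseline calibration and snapshots.

Real-world visits do not line up with trial weeks, and authorization delays
leave a documentation gap right before the first infusion.  The baseline
window is therefore chosen empirically: availability curves count, per
patient-reported element and per lookback width, the fraction of patients with
at least one dated observation in the window, and the selected width is the
narrowest one whose availability is within a tolerance of the availability at
the maximum lookback (a reproducible surrogate for "no substantial increase in
missing data").  Follow-up windows are fixed a priori: week 12 = days 70-98
(weeks 10-14), week 24 = days 140-196 (weeks 20-28).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .bundle import EhrBundle, PRO_ELEMENTS
from .screening import induction_dates


@dataclass(frozen=True)
class WindowSpec:
    label: str
    anchor_day: int  # days from induction
    lo_day: int  # inclusive offsets
    hi_day: int

    def __post_init__(self) -> None:
        if not self.lo_day <= self.anchor_day <= self.hi_day:
            raise ValueError("window must contain its anchor day")

    @property
    def width(self) -> int:
        return self.hi_day - self.lo_day


WEEK12_WINDOW = WindowSpec("week12", 84, 70, 98)
WEEK24_WINDOW = WindowSpec("week24", 168, 140, 196)


def baseline_window(lookback_weeks: int) -> WindowSpec:
    """Baseline window ending at induction day 0, extending back 7*w days."""
    return WindowSpec("baseline", 0, -7 * int(lookback_weeks), 0)


@dataclass
class AvailabilityCurve:
    """Per element and lookback width (weeks), the fraction of patients with
    >=1 observation of the element within [-7w, 0] days of induction."""

    fractions: pd.DataFrame  # index = lookback_weeks, columns = elements

    def validate(self) -> None:
        f = self.fractions
        if ((f < -1e-12) | (f > 1 + 1e-12)).any().any():
            raise ValueError("availability fractions must lie in [0, 1]")
        if (f.diff().fillna(0) < -1e-12).any().any():
            raise ValueError("availability must be non-decreasing in lookback")

    def to_frame(self) -> pd.DataFrame:
        long = self.fractions.stack().rename("fraction").reset_index()
        long.columns = ["lookback_weeks", "element", "fraction"]
        return long[["element", "lookback_weeks", "fraction"]]


def availability_curve(
    bundle: EhrBundle, eligible, max_lookback_weeks: int = 16
) -> AvailabilityCurve:
    """Availability of each PRO element as a function of baseline lookback."""
    if max_lookback_weeks < 1:
        raise ValueError("max_lookback_weeks must be >= 1")
    ids = sorted(eligible)
    if not ids:
        raise ValueError("empty eligible set")
    anchors = induction_dates(bundle, ids)
    pro = bundle.pro_observations
    pro = pro[pro["id"].isin(ids)]
    off = (pro["date"].to_numpy() - anchors.reindex(pro["id"]).to_numpy()).astype(
        "timedelta64[D]"
    ).astype(int)
    weeks = range(1, max_lookback_weeks + 1)
    out = pd.DataFrame(index=pd.Index(weeks, name="lookback_weeks"),
                       columns=list(PRO_ELEMENTS), dtype=float)
    for element in PRO_ELEMENTS:
        sel = (pro["element"] == element).to_numpy()
        for w in weeks:
            inside = sel & (off >= -7 * w) & (off <= 0)
            out.loc[w, element] = pro.loc[inside, "id"].nunique() / len(ids)
    curve = AvailabilityCurve(out)
    curve.validate()
    return curve


def select_baseline_window(curve: AvailabilityCurve, plateau_tolerance: float = 0.05) -> int:
    """Narrowest lookback (weeks) already on the availability plateau.

    Returns the smallest w such that, for every element, availability(w) >=
    (1 - plateau_tolerance) * availability(max lookback).  If no width
    qualifies (possible only with a negative tolerance), the maximum lookback
    is returned with a warning.
    """
    f = curve.fractions
    target = (1.0 - plateau_tolerance) * f.iloc[-1]
    ok = (f >= target).all(axis=1)
    if ok.any():
        return int(ok.idxmax())
    warnings.warn("no lookback reaches the availability plateau; using maximum")
    return int(f.index[-1])


def snapshot(
    bundle: EhrBundle,
    patient: str,
    window: WindowSpec,
    anchor_date: pd.Timestamp | None = None,
) -> dict[str, float | None]:
    """Element values for one patient in one window; None where unobserved.

    For each element the observation inside [lo, hi] closest in days to the
    anchor is taken; ties at equal distance break to the earlier observation.
    Covers the three PRO elements, labs (hematocrit, crp) and weight.
    """
    if anchor_date is None:
        anchor_date = induction_dates(bundle, [patient]).iloc[0]
    table = snapshot_table(bundle, [patient], window, pd.Series({patient: anchor_date}))
    row = table.loc[patient]
    return {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}


def _long_observations(bundle: EhrBundle, ids: list[str]) -> pd.DataFrame:
    pro = bundle.pro_observations
    pro = pro.loc[pro["id"].isin(ids), ["id", "element", "value", "date"]]
    labs = bundle.labs
    labs = labs.loc[labs["id"].isin(ids), ["id", "analyte", "value", "date"]].rename(
        columns={"analyte": "element"}
    )
    vit = bundle.vitals
    vit = vit.loc[vit["id"].isin(ids), ["id", "weight", "date"]].rename(
        columns={"weight": "value"}
    )
    vit = vit.assign(element="weight")[["id", "element", "value", "date"]]
    frames = [f for f in (pro, labs, vit) if len(f)]
    if not frames:
        return pro
    return pd.concat(frames, ignore_index=True)


SNAPSHOT_ELEMENTS = list(PRO_ELEMENTS) + ["hematocrit", "crp", "weight"]


def snapshot_table(
    bundle: EhrBundle, ids, window: WindowSpec, anchors: pd.Series | None = None
) -> pd.DataFrame:
    """Vectorised :func:`snapshot` over many patients.

    Returns a DataFrame indexed by patient id with one column per element
    (NaN = no observation inside the window).
    """
    ids = sorted(ids)
    if anchors is None:
        anchors = induction_dates(bundle, ids)
    obs = _long_observations(bundle, ids)
    if obs.empty:
        return pd.DataFrame(index=pd.Index(ids, name="id"), columns=SNAPSHOT_ELEMENTS,
                            dtype=float)
    off = (obs["date"].to_numpy() - anchors.reindex(obs["id"]).to_numpy()).astype(
        "timedelta64[D]"
    ).astype(int)
    obs = obs.assign(offset=off)
    obs = obs[(obs["offset"] >= window.lo_day) & (obs["offset"] <= window.hi_day)]
    obs = obs.assign(dist=(obs["offset"] - window.anchor_day).abs())
    # ties at equal distance break to the earlier observation
    obs = obs.sort_values(["id", "element", "dist", "offset"], kind="mergesort")
    best = obs.drop_duplicates(["id", "element"], keep="first")
    wide = best.pivot(index="id", columns="element", values="value").astype(float)
    wide = wide.reindex(index=ids, columns=SNAPSHOT_ELEMENTS)
    wide.index.name = "id"
    return wide
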