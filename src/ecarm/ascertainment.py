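"""Informatics ascertainment of non-PRO CDAI elements and concordance statistics.

Structured EHR data stand in for chart review wherever they can: the six
extraintestinal-complication flags come from diagnosis-code prefix sets active
in the assessment window, antidiarrheal/opiate and steroid use from medication
orders overlapping the window, and hematocrit/weight from the closest lab or
vital inside it.  Abdominal mass is a physical-exam finding that is not
reliably coded and defaults to absent — a documented limitation.  Concordance
against the manual-abstraction view is summarised as accuracy for binary
variables, mean absolute error plus per-method missingness for continuous
ones, and MAE / Pearson r-squared / remission cross-tabulation for the total
CDAI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cdai
from .bundle import EhrBundle, PERIODS, PRO_ELEMENTS
from .screening import induction_dates
from .temporal import WindowSpec, snapshot_table

#: extraintestinal-manifestation categories in CDAI order
EIM_CATEGORIES = ("fever", "arthritis", "uveitis", "anal", "skin_oral", "other_fistula")

#: editable diagnosis-code prefix sets per EIM category (ICD-9 and ICD-10 mixed)
DEFAULT_EIM_CODE_PREFIXES: dict[str, tuple[str, ...]] = {
    "fever": ("R50", "780.6"),
    "arthritis": ("M05", "M13", "714", "716"),
    "uveitis": ("H20", "364.0"),
    "anal": ("K60", "K61", "565"),
    "skin_oral": ("L52", "L88", "K12.0", "528.2", "695.2"),
    "other_fistula": ("K63.2", "N32.1", "569.81"),
}

BINARY_VARIABLES = list(EIM_CATEGORIES) + ["antidiarrheal", "steroid"]


def _flag_frame(
    bundle: EhrBundle, ids: list[str], window: WindowSpec, anchors: pd.Series,
    code_prefixes: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Binary flags (EIM categories + med-use) for all patients in one window."""
    out = pd.DataFrame(0.0, index=pd.Index(ids, name="id"), columns=BINARY_VARIABLES)
    dx = bundle.diagnoses
    dx = dx[dx["id"].isin(ids)]
    if len(dx):
        off = (dx["date"].to_numpy() - anchors.reindex(dx["id"]).to_numpy()).astype(
            "timedelta64[D]"
        ).astype(int)
        in_win = (off >= window.lo_day) & (off <= window.hi_day)
        codes = dx["code"].astype(str)
        for cat, prefixes in code_prefixes.items():
            hit = codes.str.startswith(prefixes).to_numpy() & in_win
            flagged = dx.loc[hit, "id"].unique()
            out.loc[out.index.isin(flagged), cat] = 1.0
    meds = bundle.medications
    meds = meds[meds["id"].isin(ids)]
    if len(meds):
        anchor = anchors.reindex(meds["id"]).to_numpy()
        s_off = (meds["start_date"].to_numpy() - anchor).astype("timedelta64[D]").astype(int)
        e_off = (meds["end_date"].to_numpy() - anchor).astype("timedelta64[D]").astype(int)
        intersects = (s_off <= window.hi_day) & (e_off >= window.lo_day)
        adio = (meds["drug_class"] == "antidiarrheal_opiate").to_numpy() & intersects
        steroid = meds["drug_class"].isin(["oral_steroid", "iv_steroid"]).to_numpy() & intersects
        out.loc[out.index.isin(meds.loc[adio, "id"].unique()), "antidiarrheal"] = 1.0
        out.loc[out.index.isin(meds.loc[steroid, "id"].unique()), "steroid"] = 1.0
    return out


def ascertain_nonpro3(
    bundle: EhrBundle,
    patient: str,
    window: WindowSpec,
    code_prefixes: dict[str, tuple[str, ...]] | None = None,
) -> cdai.CdaiComponents:
    """Non-PRO CDAI components for one patient from structured data only.

    Missing labs/vitals propagate as None; the PRO fields remain None (they
    are filled from observations or abstraction elsewhere).
    """
    prefixes = code_prefixes or DEFAULT_EIM_CODE_PREFIXES
    anchors = induction_dates(bundle, [patient])
    flags = _flag_frame(bundle, [patient], window, anchors, prefixes).loc[patient]
    snap = snapshot_table(bundle, [patient], window, anchors).loc[patient]
    prow = bundle.patients.loc[bundle.patients["id"] == patient].iloc[0]
    return cdai.CdaiComponents(
        eim_count=float(flags[list(EIM_CATEGORIES)].sum()),
        antidiarrheal_use=float(flags["antidiarrheal"]),
        abdominal_mass=0.0,
        hematocrit=None if pd.isna(snap["hematocrit"]) else float(snap["hematocrit"]),
        sex=prow["sex"],
        weight=None if pd.isna(snap["weight"]) else float(snap["weight"]),
        standard_weight=float(prow["standard_weight"]),
    )


def build_cohort_matrix(
    bundle: EhrBundle,
    ids,
    windows: dict[str, WindowSpec],
    code_prefixes: dict[str, tuple[str, ...]] | None = None,
):
    """Patients x (element@period) matrix with missingness, for imputation.

    One row per patient; per period: PRO dailies, hematocrit, weight, CRP
    (NaN where no observation fell in the window) plus informatics flags
    (never missing); static demographics appended once.  Returns a
    :class:`~ecarm.imputation.CohortMatrix`.
    """
    from .imputation import CohortMatrix  # local import to avoid a cycle

    prefixes = code_prefixes or DEFAULT_EIM_CODE_PREFIXES
    ids = sorted(ids)
    anchors = induction_dates(bundle, ids)
    parts = []
    col_types: dict[str, str] = {}
    for period, window in windows.items():
        snap = snapshot_table(bundle, ids, window, anchors)
        snap = snap.rename(columns={"abdominal_pain": "pain"})
        snap = snap[["pain", "diarrhea", "wellbeing", "hematocrit", "crp", "weight"]]
        flags = _flag_frame(bundle, ids, window, anchors, prefixes)
        block = pd.concat([snap, flags], axis=1)
        block.columns = [f"{c}__{period}" for c in block.columns]
        for c in snap.columns:
            col_types[f"{c}__{period}"] = "continuous"
        for c in flags.columns:
            col_types[f"{c}__{period}"] = "categorical"
        parts.append(block)
    pat = bundle.patients.set_index("id").reindex(ids)
    static = pd.DataFrame(index=pd.Index(ids, name="id"))
    static["age"] = (anchors - pat["birth_date"]).dt.days / 365.25
    col_types["age"] = "continuous"
    static["sex"] = pat["sex"]
    col_types["sex"] = "categorical"
    static["standard_weight"] = pat["standard_weight"].astype(float)
    col_types["standard_weight"] = "continuous"
    for extra, kind in (
        ("disease_duration", "continuous"),
        ("prior_biologic", "categorical"),
        ("montreal", "categorical"),
    ):
        if extra in pat.columns:
            static[extra] = pat[extra]
            col_types[extra] = kind
    values = pd.concat(parts + [static], axis=1)
    return CohortMatrix(values, col_types)


_CLIP = {"pain": (0.0, 3.0), "wellbeing": (0.0, 4.0), "diarrhea": (0.0, None),
         "hematocrit": (1.0, 99.0)}


def components_from_row(row: pd.Series, period: str) -> cdai.CdaiComponents:
    """Assemble CDAI components for one matrix row at one period.

    Imputed continuous values are clipped back into their declared ranges and
    flags rounded to {0,1}; single-visit daily PROs are expanded by the x7
    convention.
    """
    def get(col, clip=None):
        v = row.get(f"{col}__{period}")
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        v = float(v)
        if clip:
            lo, hi = clip
            v = max(v, lo) if lo is not None else v
            v = min(v, hi) if hi is not None else v
        return v

    eims = [get(c) for c in EIM_CATEGORIES]
    eim_count = None if any(e is None for e in eims) else float(sum(round(e) for e in eims))
    adio = get("antidiarrheal")
    stools = get("diarrhea", _CLIP["diarrhea"])
    pain = get("pain", _CLIP["pain"])
    well = get("wellbeing", _CLIP["wellbeing"])
    return cdai.CdaiComponents(
        liquid_stools_7d=None if stools is None else 7.0 * stools,
        abdominal_pain_7d=None if pain is None else 7.0 * pain,
        wellbeing_7d=None if well is None else 7.0 * well,
        eim_count=eim_count,
        antidiarrheal_use=None if adio is None else float(round(adio)),
        abdominal_mass=0.0,
        hematocrit=get("hematocrit", _CLIP["hematocrit"]),
        sex=row.get("sex"),
        weight=get("weight"),
        standard_weight=float(row["standard_weight"]),
    )


def cdai_scores(values: pd.DataFrame, period: str) -> pd.Series:
    """Total CDAI per patient at one period from a (completed) matrix."""
    return values.apply(
        lambda row: cdai.compute_cdai(components_from_row(row, period)), axis=1
    )


# ---------------------------------------------------------------------------
# concordance against the manual-abstraction view
# ---------------------------------------------------------------------------

def abstraction_view(bundle: EhrBundle, ids, period: str) -> pd.DataFrame:
    """Wide manual-review values (rows = patients, columns = elements)."""
    ab = bundle.abstraction
    ab = ab[(ab["period"] == period) & (ab["id"].isin(set(ids)))]
    if ab.empty:
        return pd.DataFrame(index=pd.Index(sorted(ids), name="id"))
    wide = ab.pivot(index="id", columns="element", values="value")
    wide = wide.reindex(sorted(ids))
    return wide.apply(lambda s: pd.to_numeric(s, errors="coerce"))


def concordance_binary(informatic: pd.DataFrame, manual: pd.DataFrame) -> pd.Series:
    """Complete-case agreement per binary variable (manual = gold standard)."""
    out = {}
    for col in informatic.columns.intersection(manual.columns):
        a = pd.to_numeric(informatic[col], errors="coerce")
        b = pd.to_numeric(manual[col], errors="coerce").reindex(a.index)
        both = a.notna() & b.notna()
        if both.sum() == 0:
            raise ValueError(f"{col}: zero comparable pairs")
        out[col] = float((a[both].round() == b[both].round()).mean())
    return pd.Series(out, name="accuracy")


def concordance_continuous(informatic: pd.DataFrame, manual: pd.DataFrame) -> pd.DataFrame:
    """MAE over doubly-observed pairs plus per-method missing fractions.

    MAE is NaN (flagged, not an error) when no pair is doubly observed.
    """
    rows = []
    for col in informatic.columns.intersection(manual.columns):
        a = pd.to_numeric(informatic[col], errors="coerce")
        b = pd.to_numeric(manual[col], errors="coerce").reindex(a.index)
        both = a.notna() & b.notna()
        mae = float((a[both] - b[both]).abs().mean()) if both.any() else np.nan
        rows.append(
            {
                "variable": col,
                "mae": mae,
                "n_pairs": int(both.sum()),
                "missing_informatics": float(a.isna().mean()),
                "missing_manual": float(b.isna().mean()),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def concordance_total(
    informatic_cdai: pd.Series,
    manual_cdai: pd.Series,
    remission_threshold: float = cdai.DEFAULT_THRESHOLDS.remission,
) -> dict:
    """Total-CDAI agreement: MAE, Pearson r^2, remission counts per method.

    Remission denominators are reported per method (all non-missing scores
    under that method), which may legitimately differ.
    """
    a = pd.to_numeric(informatic_cdai, errors="coerce")
    b = pd.to_numeric(manual_cdai, errors="coerce").reindex(a.index)
    both = a.notna() & b.notna()
    n = int(both.sum())
    if n < 3:
        raise ValueError("need >=3 doubly-observed CDAI pairs")
    x, y = a[both], b[both]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on one side; r^2 undefined")
    r = stats.pearsonr(x, y).statistic
    rem_inf = a <= remission_threshold
    rem_man = b <= remission_threshold
    return {
        "mae": float((x - y).abs().mean()),
        "r2": float(r * r),
        "n_pairs": n,
        "remission_informatics": int(rem_inf[a.notna()].sum()),
        "denominator_informatics": int(a.notna().sum()),
        "remission_manual": int(rem_man[b.notna()].sum()),
        "denominator_manual": int(b.notna().sum()),
        "crosstab": {
            "both_remission": int((rem_inf & rem_man & both).sum()),
            "informatics_only": int((rem_inf & ~rem_man & both).sum()),
            "manual_only": int((~rem_inf & rem_man & both).sum()),
            "neither": int((~rem_inf & ~rem_man & both).sum()),
        },
    }


@dataclass
class ConcordanceReport:
    binary: pd.DataFrame = field(default_factory=pd.DataFrame)
    continuous: pd.DataFrame = field(default_factory=pd.DataFrame)
    total: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.binary.to_csv(directory / "concordance_binary.csv", index=False)
        self.continuous.to_csv(directory / "concordance_continuous.csv", index=False)
        self.total.to_csv(directory / "concordance_total.csv", index=False)


def _informatics_view(bundle, ids, window, prefixes) -> pd.DataFrame:
    anchors = induction_dates(bundle, ids)
    snap = snapshot_table(bundle, ids, window, anchors).rename(
        columns={"abdominal_pain": "abdominal_pain"}
    )
    flags = _flag_frame(bundle, ids, window, anchors, prefixes)
    return pd.concat([snap, flags], axis=1)


def _total_scores(view: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    """Complete-case total CDAI from a wide element view (NaN when incomplete)."""
    pat = patients.set_index("id")
    out = {}
    for pid, row in view.iterrows():
        vals = row.reindex(
            ["abdominal_pain", "diarrhea", "wellbeing", "hematocrit", "weight"]
            + list(EIM_CATEGORIES) + ["antidiarrheal"]
        )
        if vals.isna().any():
            out[pid] = np.nan
            continue
        comp = cdai.CdaiComponents(
            liquid_stools_7d=7.0 * float(vals["diarrhea"]),
            abdominal_pain_7d=7.0 * float(vals["abdominal_pain"]),
            wellbeing_7d=7.0 * float(vals["wellbeing"]),
            eim_count=float(sum(round(float(vals[c])) for c in EIM_CATEGORIES)),
            antidiarrheal_use=float(round(float(vals["antidiarrheal"]))),
            abdominal_mass=0.0,
            hematocrit=float(vals["hematocrit"]),
            sex=pat.loc[pid, "sex"],
            weight=float(vals["weight"]),
            standard_weight=float(pat.loc[pid, "standard_weight"]),
        )
        out[pid] = cdai.compute_cdai(comp)
    return pd.Series(out)


def concordance_report(
    bundle: EhrBundle,
    ids,
    windows: dict[str, WindowSpec],
    code_prefixes: dict[str, tuple[str, ...]] | None = None,
) -> ConcordanceReport:
    """Run the full informatics-vs-manual comparison over the given periods.

    For the total CDAI, the PRO elements are taken from the manual view on
    both sides (only the non-PRO elements differ by method), mirroring how a
    chart-review gold standard is used in practice.
    """
    prefixes = code_prefixes or DEFAULT_EIM_CODE_PREFIXES
    ids = sorted(ids)
    bin_rows, cont_rows, tot_rows = [], [], []
    for period, window in windows.items():
        inf = _informatics_view(bundle, ids, window, prefixes)
        man = abstraction_view(bundle, ids, period)
        bin_cols = [c for c in BINARY_VARIABLES if c in man.columns]
        if bin_cols:
            acc = concordance_binary(inf[bin_cols], man[bin_cols])
            for var, a in acc.items():
                bin_rows.append({"variable": var, "period": period, "accuracy": a})
        cont_cols = [c for c in ("hematocrit", "weight") if c in man.columns]
        if cont_cols:
            cc = concordance_continuous(inf[cont_cols], man[cont_cols])
            for var, row in cc.iterrows():
                cont_rows.append({"variable": var, "period": period, **row.to_dict()})
        # total CDAI: shared manual PRO3, differing non-PRO3 source
        pro_cols = [c for c in PRO_ELEMENTS if c in man.columns]
        if len(pro_cols) == 3:
            inf_mixed = inf.copy()
            inf_mixed[pro_cols] = man[pro_cols]
            try:
                tot = concordance_total(
                    _total_scores(inf_mixed, bundle.patients),
                    _total_scores(man, bundle.patients),
                )
                tot_rows.append({"period": period, **{k: v for k, v in tot.items()
                                                      if k != "crosstab"}})
            except ValueError:
                pass
    return ConcordanceReport(
        binary=pd.DataFrame(bin_rows),
        continuous=pd.DataFrame(cont_rows),
        total=pd.DataFrame(tot_rows),
    )
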