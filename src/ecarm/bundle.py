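"""The linked-table EHR container shared by every pipeline stage.

An :class:`EhrBundle` is a set of longitudinal flat tables, one row per dated
clinical fact, in an intentionally bespoke OMOP-like dialect: patients,
diagnoses (ICD-9/10-style codes), medication orders (with class, dose, route
and an interval), labs, vitals, patient-reported-outcome observations,
surgeries, and an ``abstraction`` table that plays the role of the manual
chart-review view (element values per assessment period).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: medication classes recognised throughout the pipeline
DRUG_CLASSES = (
    "ustekinumab",
    "iv_steroid",
    "oral_steroid",
    "immunomodulator",
    "antibiotic_cd",
    "five_asa",
    "antidiarrheal_opiate",
    "other",
)

PRO_ELEMENTS = ("abdominal_pain", "diarrhea", "wellbeing")
PERIODS = ("baseline", "week12", "week24")

_DATE_COLS = {
    "patients": ["birth_date"],
    "diagnoses": ["date"],
    "medications": ["start_date", "end_date"],
    "labs": ["date"],
    "vitals": ["date"],
    "pro_observations": ["date"],
    "surgeries": ["date"],
    "abstraction": [],
}

_SCHEMAS = {
    "patients": ["id", "birth_date", "sex", "standard_weight"],
    "diagnoses": ["id", "code", "date"],
    "medications": ["id", "drug_name", "drug_class", "dose", "route", "start_date", "end_date"],
    "labs": ["id", "analyte", "value", "unit", "date"],
    "vitals": ["id", "weight", "date"],
    "pro_observations": ["id", "element", "value", "date"],
    "surgeries": ["id", "procedure", "date"],
    "abstraction": ["id", "element", "value", "period"],
}


def _empty(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in _SCHEMAS[table]})
    for c in _DATE_COLS[table]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


@dataclass
class EhrBundle:
    patients: pd.DataFrame = field(default_factory=lambda: _empty("patients"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty("diagnoses"))
    medications: pd.DataFrame = field(default_factory=lambda: _empty("medications"))
    labs: pd.DataFrame = field(default_factory=lambda: _empty("labs"))
    vitals: pd.DataFrame = field(default_factory=lambda: _empty("vitals"))
    pro_observations: pd.DataFrame = field(default_factory=lambda: _empty("pro_observations"))
    surgeries: pd.DataFrame = field(default_factory=lambda: _empty("surgeries"))
    abstraction: pd.DataFrame = field(default_factory=lambda: _empty("abstraction"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def validate(self) -> None:
        """Check referential integrity, date ordering, and PRO value ranges."""
        known = set(self.patients["id"])
        for name, df in self.tables().items():
            if name == "patients":
                continue
            orphans = set(df["id"]) - known
            if orphans:
                raise ValueError(f"{name}: ids not in patients table: {sorted(orphans)[:5]}")
        meds = self.medications
        if len(meds) and (meds["end_date"] < meds["start_date"]).any():
            raise ValueError("medications: end_date before start_date")
        pro = self.pro_observations
        if len(pro):
            v = pd.to_numeric(pro["value"])
            if (v < 0).any():
                raise ValueError("pro_observations: negative values")
            pain = v[pro["element"] == "abdominal_pain"]
            well = v[pro["element"] == "wellbeing"]
            if len(pain) and pain.max() > 3:
                raise ValueError("abdominal_pain daily values must be 0-3")
            if len(well) and well.max() > 4:
                raise ValueError("wellbeing daily values must be 0-4")

    def write(self, directory: str | Path) -> None:
        """Write one CSV per table (header row, ISO-8601 dates, UTF-8)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            out = df.copy()
            for c in _DATE_COLS[name]:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
            out.to_csv(directory / f"{name}.csv", index=False, encoding="utf-8")

    @classmethod
    def read(cls, directory: str | Path) -> "EhrBundle":
        directory = Path(directory)
        kwargs = {}
        for name in _SCHEMAS:
            path = directory / f"{name}.csv"
            if not path.exists():
                continue
            df = pd.read_csv(path, parse_dates=_DATE_COLS[name])
            if df.empty:
                df = _empty(name)
            kwargs[name] = df
        return cls(**kwargs)
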