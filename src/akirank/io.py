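"""Reading and writing cohort tables.

Two delimited files describe a cohort:

* ``patients.csv`` — one row per patient (arm, covariates, event days);
* ``labs.csv`` — long format, one row per observation:
  ``patient_id, analyte, time_h, value, unit``.

Ingest validates schemas and value constraints and reports every violation
with its row number.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .records import LabSeries, PatientRecord

PATIENT_COLUMNS = [
    "id", "arm", "age", "sex", "icu_type", "apache2", "septic_shock",
    "aki_on_enrollment", "weight", "baseline_scr", "death_day",
    "krt_start_day", "icu_days", "hospital_days", "egfr", "risk_factors",
]
LAB_COLUMNS = ["patient_id", "analyte", "time_h", "value", "unit"]


class ValidationError(ValueError):
    """Schema or value violations in ingested tables, itemized by row."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("input validation failed:\n" + "\n".join(self.problems))


def patients_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        rows.append({
            "id": p.id, "arm": p.arm, "age": round(p.age, 1), "sex": p.sex,
            "icu_type": p.icu_type, "apache2": p.apache2,
            "septic_shock": int(p.septic_shock),
            "aki_on_enrollment": int(p.aki_on_enrollment),
            "weight": round(p.weight, 1), "baseline_scr": round(p.baseline_scr, 4),
            "death_day": "" if p.death_day is None else p.death_day,
            "krt_start_day": "" if p.krt_start_day is None else p.krt_start_day,
            "icu_days": p.icu_days, "hospital_days": p.hospital_days,
            "egfr": "" if p.egfr is None else round(p.egfr, 1),
            "risk_factors": ";".join(p.risk_factors),
        })
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def labs_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        for analyte, series in sorted(p.labs.items()):
            for t, v in zip(series.times_h, series.values):
                rows.append({
                    "patient_id": p.id, "analyte": analyte,
                    "time_h": round(float(t), 3), "value": round(float(v), 6),
                    "unit": series.unit,
                })
    return pd.DataFrame(rows, columns=LAB_COLUMNS)


def write_cohort(patients: Sequence[PatientRecord], out_dir: str) -> Dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "patients": os.path.join(out_dir, "patients.csv"),
        "labs": os.path.join(out_dir, "labs.csv"),
    }
    patients_frame(patients).to_csv(paths["patients"], index=False)
    labs_frame(patients).to_csv(paths["labs"], index=False)
    return paths


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort(patients_path: str, labs_path: str) -> List[PatientRecord]:
    """Load a cohort from the two delimited tables, validating both."""
    problems: List[str] = []
    pdf = pd.read_csv(patients_path)
    ldf = pd.read_csv(labs_path)

    missing = [c for c in PATIENT_COLUMNS if c not in pdf.columns]
    if missing:
        problems.append(f"patients: missing columns {missing}")
    missing = [c for c in LAB_COLUMNS if c not in ldf.columns]
    if missing:
        problems.append(f"labs: missing columns {missing}")
    if problems:
        raise ValidationError(problems)

    if pdf["id"].duplicated().any():
        dups = pdf.loc[pdf["id"].duplicated(), "id"].tolist()
        problems.append(f"patients: duplicate ids {dups}")
    known = set(pdf["id"])
    for i, row in ldf.iterrows():
        if row["patient_id"] not in known:
            problems.append(f"labs row {i}: unknown patient_id {row['patient_id']!r}")
        if not np.isfinite(row["value"]) or row["value"] <= 0:
            problems.append(
                f"labs row {i}: non-positive value {row['value']!r} for "
                f"{row['analyte']!r}"
            )
        if not np.isfinite(row["time_h"]) or row["time_h"] < 0:
            problems.append(f"labs row {i}: invalid time_h {row['time_h']!r}")
    for i, row in pdf.iterrows():
        if row["baseline_scr"] <= 0:
            problems.append(f"patients row {i}: non-positive baseline_scr")
        if row["weight"] <= 0:
            problems.append(f"patients row {i}: non-positive weight")
    if problems:
        raise ValidationError(problems)

    patients: List[PatientRecord] = []
    grouped = dict(tuple(ldf.groupby("patient_id", sort=False)))
    for _, row in pdf.iterrows():
        labs: Dict[str, LabSeries] = {}
        sub = grouped.get(row["id"])
        if sub is not None:
            for analyte, obs in sub.groupby("analyte", sort=False):
                obs = obs.sort_values("time_h")
                labs[analyte] = LabSeries(
                    analyte, str(obs["unit"].iloc[0]),
                    obs["time_h"].to_numpy(float), obs["value"].to_numpy(float),
                )
        rf = row["risk_factors"]
        factors = tuple(str(rf).split(";")) if isinstance(rf, str) and rf else ()
        patients.append(PatientRecord(
            id=str(row["id"]), arm=str(row["arm"]), age=float(row["age"]),
            sex=str(row["sex"]), icu_type=str(row["icu_type"]),
            apache2=int(row["apache2"]), septic_shock=bool(row["septic_shock"]),
            aki_on_enrollment=bool(row["aki_on_enrollment"]),
            weight=float(row["weight"]), baseline_scr=float(row["baseline_scr"]),
            death_day=_opt_int(row["death_day"]),
            krt_start_day=_opt_int(row["krt_start_day"]),
            icu_days=int(row["icu_days"]), hospital_days=int(row["hospital_days"]),
            egfr=_opt_float(row["egfr"]), risk_factors=factors, labs=labs,
        ))
    return patients
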