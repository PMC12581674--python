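"""Core in-memory records: lab time series and enrolled patients.

Time is measured in hours from enrollment; study day ``d`` spans the
half-open bin ``[24*d, 24*(d+1))`` hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

HOURS_PER_DAY = 24.0

#: canonical analyte names and units used throughout the package
ANALYTE_UNITS = {
    "scr": "mg/dL",
    "25d": "ng/mL",
    "125d": "pg/mL",
    "calcium": "mg/dL",
    "phosphate": "mg/dL",
    "uop": "mL/kg/h",
}


@dataclass(frozen=True)
class LabSeries:
    """Timestamped measurements of a single analyte for one patient.

    Parameters
    ----------
    analyte :
        Analyte name (e.g. ``"scr"``, ``"25d"``, ``"uop"``).
    unit :
        Measurement unit, e.g. ``"mg/dL"``.
    times_h :
        Observation times in hours from enrollment, strictly increasing.
    values :
        Measured values, strictly positive for concentrations.
    """

    analyte: str
    unit: str
    times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times_h and values must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.analyte}: observation times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError(f"{self.analyte}: concentration values must be positive")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times_h.size)

    def value_on_day(self, day: int) -> Optional[float]:
        """First observed value in the day bin ``[24*day, 24*day+24)``, or None."""
        lo, hi = HOURS_PER_DAY * day, HOURS_PER_DAY * (day + 1)
        mask = (self.times_h >= lo) & (self.times_h < hi)
        if not mask.any():
            return None
        return float(self.values[mask][0])

    def last_at_or_before(self, t: float) -> Optional[float]:
        idx = np.searchsorted(self.times_h, t, side="right") - 1
        if idx < 0:
            return None
        return float(self.values[idx])

    def window(self, t0: float, t1: float) -> "LabSeries":
        """Observations with time in the closed interval ``[t0, t1]``."""
        mask = (self.times_h >= t0) & (self.times_h <= t1)
        return LabSeries(self.analyte, self.unit, self.times_h[mask], self.values[mask])

    def truncated(self, t_max: float) -> "LabSeries":
        """Observations with time ``<= t_max``."""
        mask = self.times_h <= t_max
        return LabSeries(self.analyte, self.unit, self.times_h[mask], self.values[mask])


@dataclass
class PatientRecord:
    """One enrolled patient: arm, covariates, event days, daily lab series."""

    id: str
    arm: str
    age: float
    sex: str  # "F" | "M"
    icu_type: str  # "medical" | "surgical"
    apache2: int
    septic_shock: bool
    aki_on_enrollment: bool
    weight: float  # kg
    baseline_scr: float  # mg/dL
    death_day: Optional[int] = None  # day index within 28-day follow-up
    krt_start_day: Optional[int] = None
    icu_days: int = 0
    hospital_days: int = 0
    egfr: Optional[float] = None  # mL/min/1.73m2, input field (not computed)
    risk_factors: tuple = ()
    labs: dict = field(default_factory=dict)  # analyte -> LabSeries

    def __post_init__(self) -> None:
        if self.baseline_scr <= 0:
            raise ValueError(f"{self.id}: baseline_scr must be positive")
        if self.weight <= 0:
            raise ValueError(f"{self.id}: weight must be positive")
        for day in (self.death_day, self.krt_start_day):
            if day is not None and day < 0:
                raise ValueError(f"{self.id}: event days must be >= 0")

    @property
    def died_7d(self) -> bool:
        return self.death_day is not None and self.death_day <= 7

    @property
    def krt_7d(self) -> bool:
        return self.krt_start_day is not None and self.krt_start_day <= 7

    @property
    def died_28d(self) -> bool:
        return self.death_day is not None and self.death_day < 28

    def lab(self, analyte: str) -> Optional[LabSeries]:
        return self.labs.get(analyte)


def check_labs_censored(patients: Iterable[PatientRecord]) -> None:
    """Raise if any patient has lab observations after their death day."""
    for p in patients:
        if p.death_day is None:
            continue
        t_max = HOURS_PER_DAY * (p.death_day + 1)
        for series in p.labs.values():
            if series.times_h.size and series.times_h[-1] >= t_max:
                raise ValueError(f"{p.id}: lab observations after death day {p.death_day}")
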