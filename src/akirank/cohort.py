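"""Synthetic three-arm ICU cohort generator.

Emulates the statistical structure the trial analysis assumes: stratified
permuted-block randomization (blocks of 3, stratified by AKI on
enrollment), arm-specific 7-day death/KRT risks, serum creatinine
trajectories with multiplicative noise around a latent drift, per-arm
vitamin D metabolite pharmacokinetic fold-change schedules, daily
calcium/phosphate, and hourly urine output.

All randomness flows from ``config.seed`` through a spawned
``numpy.random.Generator`` per stage, so cohorts are reproducible
field-for-field and each stage is independently reproducible.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ARMS, CohortConfig
from .records import HOURS_PER_DAY, LabSeries, PatientRecord

__all__ = [
    "assign_randomization",
    "generate_cohort",
    "simulate_scr_trajectory",
    "simulate_vitd_pk",
    "simulate_events",
    "simulate_mineral_labs",
    "simulate_uop",
]

# stable stream indices for per-stage generators spawned off the root seed
_STREAMS = {
    "covariates": 0,
    "randomization": 1,
    "events": 2,
    "scr": 3,
    "vitd": 4,
    "minerals": 5,
    "uop": 6,
}


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=np.uint64(config.seed), counter=[0, 0, 0, _STREAMS[stream]])
    )


def assign_randomization(patient_strata: Sequence[bool], seed: int) -> List[str]:
    """Assign arms by permuted blocks of 3 within each AKI stratum.

    Within each stratum, consecutive patients fill shuffled blocks
    containing each arm exactly once, so arm sizes within a stratum never
    differ by more than one.
    """
    rng = np.random.default_rng(seed)
    arms = np.array(ARMS)
    assignments: List[Optional[str]] = [None] * len(patient_strata)
    for stratum in (False, True):
        idx = [i for i, s in enumerate(patient_strata) if bool(s) == stratum]
        n_blocks = math.ceil(len(idx) / 3)
        labels: List[str] = []
        for _ in range(n_blocks):
            labels.extend(arms[rng.permutation(3)])
        for i, lab in zip(idx, labels):
            assignments[i] = lab
    return [str(a) for a in assignments]


def simulate_events(patient: PatientRecord, config: CohortConfig,
                    rng: Optional[np.random.Generator] = None) -> PatientRecord:
    """Draw death / KRT event days for one patient from arm-specific risks.

    7-day events land uniformly on days 0..7; late deaths (beyond day 7 but
    within the 28-day cumulative risk) land uniformly on days 8..27.
    ICU/hospital stays are drawn consistent with the events.
    """
    rng = rng if rng is not None else _rng(config, "events")
    arm = patient.arm
    if arm not in config.death_risk_7d_by_arm:
        raise ValueError(f"unknown arm {arm!r}")

    u_death, u_krt, u_late = rng.uniform(size=3)
    p7 = config.death_risk_7d_by_arm[arm]
    p28 = config.death_risk_28d_by_arm[arm]
    death_day: Optional[int] = None
    if u_death < p7:
        death_day = int(rng.integers(0, 8))
    elif p28 > p7 and u_late < (p28 - p7) / (1.0 - p7):
        death_day = int(rng.integers(8, 28))
    if u_krt < config.krt_risk_7d_by_arm[arm]:
        krt_day = int(rng.integers(0, 8))
        if death_day is not None:
            krt_day = min(krt_day, death_day)
        patient.krt_start_day = krt_day
    patient.death_day = death_day

    # length of stay consistent with events
    if death_day is not None:
        patient.icu_days = min(death_day + 1, config.followup_days)
        patient.hospital_days = patient.icu_days
    else:
        icu = int(np.ceil(rng.lognormal(math.log(6.0), 0.6)))
        ward = int(np.ceil(rng.lognormal(math.log(6.0), 0.7)))
        patient.icu_days = min(icu, config.followup_days)
        patient.hospital_days = min(icu + ward, config.followup_days)
    return patient


def simulate_scr_trajectory(patient: PatientRecord, config: CohortConfig,
                            rng: Optional[np.random.Generator] = None) -> LabSeries:
    """Daily serum creatinine for days 0..horizon (censored at death).

    Day 0 equals the enrollment baseline exactly; later days follow
    ``baseline * (1 + drift/100)^d`` with i.i.d. mean-one lognormal daily
    noise. The patient's drift is a state draw (improving/stable/worsening)
    plus a per-patient jitter.
    """
    rng = rng if rng is not None else _rng(config, "scr")
    model = config.scr
    states = sorted(model.state_probs)
    probs = np.array([model.state_probs[s] for s in states])
    state = states[int(rng.choice(len(states), p=probs / probs.sum()))]
    drift = model.drift_by_state[state] + rng.normal(0.0, model.drift_jitter_sd)

    last_day = config.horizon_days
    if patient.death_day is not None:
        last_day = min(last_day, patient.death_day)
    days = np.arange(0, last_day + 1)
    sigma = model.noise_sd / 100.0
    noise = np.ones_like(days, dtype=float)
    if sigma > 0 and days.size > 1:
        # mean-one lognormal noise; day 0 is the measured baseline itself
        noise[1:] = rng.lognormal(-0.5 * sigma**2, sigma, size=days.size - 1)
    values = patient.baseline_scr * (1.0 + drift / 100.0) ** days * noise
    return LabSeries("scr", "mg/dL", days * HOURS_PER_DAY, values)


def simulate_vitd_pk(arm: str, baseline_25d: float, baseline_125d: float,
                     config: CohortConfig,
                     rng: Optional[np.random.Generator] = None,
                     death_day: Optional[int] = None) -> Tuple[LabSeries, LabSeries]:
    """Daily 25D and 1,25D series: deterministic per-arm fold-change schedule
    times mean-one lognormal noise (day 0 is the measured baseline).
    """
    if arm not in config.pk_multipliers:
        raise ValueError(f"unknown arm {arm!r}")
    if baseline_25d <= 0 or baseline_125d <= 0:
        raise ValueError("metabolite baselines must be positive")
    rng = rng if rng is not None else _rng(config, "vitd")
    cv = config.pk_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    out = []
    for analyte, baseline in (("25d", baseline_25d), ("125d", baseline_125d)):
        mults = np.asarray(config.pk_multipliers[arm][analyte], dtype=float)
        last_day = min(config.horizon_days, len(mults) - 1)
        if death_day is not None:
            last_day = min(last_day, death_day)
        days = np.arange(0, last_day + 1)
        noise = np.ones_like(days, dtype=float)
        if sigma > 0 and days.size > 1:
            noise[1:] = rng.lognormal(-0.5 * sigma**2, sigma, size=days.size - 1)
        values = baseline * mults[: days.size] * noise
        unit = "ng/mL" if analyte == "25d" else "pg/mL"
        out.append(LabSeries(analyte, unit, days * HOURS_PER_DAY, values))
    return out[0], out[1]


def simulate_mineral_labs(patient: PatientRecord, config: CohortConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> Tuple[LabSeries, LabSeries]:
    """Daily serum calcium and phosphate (days 0..horizon, censored at death):
    patient-level mean with additive arm offset plus daily noise."""
    rng = rng if rng is not None else _rng(config, "minerals")
    m = config.minerals
    last_day = config.horizon_days
    if patient.death_day is not None:
        last_day = min(last_day, patient.death_day)
    days = np.arange(0, last_day + 1)

    ca_level = rng.normal(m.ca_mean + m.ca_arm_offset.get(patient.arm, 0.0), m.ca_between_sd)
    po4_level = rng.normal(m.po4_mean + m.po4_arm_offset.get(patient.arm, 0.0), m.po4_between_sd)
    ca = np.clip(ca_level + rng.normal(0.0, m.ca_within_sd, size=days.size), 5.0, None)
    po4 = np.clip(po4_level + rng.normal(0.0, m.po4_within_sd, size=days.size), 0.5, None)
    return (
        LabSeries("calcium", "mg/dL", days * HOURS_PER_DAY, ca),
        LabSeries("phosphate", "mg/dL", days * HOURS_PER_DAY, po4),
    )


def simulate_uop(patient: PatientRecord, config: CohortConfig,
                 rng: Optional[np.random.Generator] = None) -> LabSeries:
    """Hourly urine output (mL/kg/h) for the first 24h after enrollment,
    sufficient for the 6-h and 12-h oliguria run rules."""
    rng = rng if rng is not None else _rng(config, "uop")
    u = config.uop
    level = rng.lognormal(u.log_mean, u.log_sd)
    hours = np.arange(1, 25, dtype=float)
    if patient.death_day is not None:
        # censor at death: day d covers hours [24d, 24d+24)
        hours = hours[hours < HOURS_PER_DAY * (patient.death_day + 1)]
    noise = (
        rng.lognormal(-0.5 * u.hourly_noise_sd**2, u.hourly_noise_sd, size=hours.size)
        if u.hourly_noise_sd > 0
        else np.ones(hours.size)
    )
    return LabSeries("uop", "mL/kg/h", hours, level * noise)


def _draw_covariates(n: int, config: CohortConfig, rng: np.random.Generator) -> List[dict]:
    covs = []
    p25 = config.vitd_baseline_params["25d"]
    p125 = config.vitd_baseline_params["125d"]
    for i in range(n):
        covs.append(
            dict(
                age=float(np.clip(rng.normal(60.0, 15.0), 18.0, 95.0)),
                sex="F" if rng.uniform() < 0.45 else "M",
                icu_type="medical" if rng.uniform() < 0.6 else "surgical",
                apache2=int(np.clip(round(rng.normal(22.0, 7.0)), 0, 55)),
                septic_shock=bool(rng.uniform() < 0.70),
                weight=float(np.clip(rng.normal(80.0, 18.0), 40.0, 160.0)),
                baseline_scr=float(
                    rng.lognormal(config.baseline_scr_log_mean, config.baseline_scr_log_sd)
                ),
                baseline_25d=float(rng.lognormal(p25["mu"], p25["sigma"])),
                baseline_125d=float(rng.lognormal(p125["mu"], p125["sigma"])),
                aki_on_enrollment=bool(rng.uniform() < config.aki_prevalence),
            )
        )
    return covs


def generate_cohort(config: CohortConfig) -> List[PatientRecord]:
    """Generate a randomized three-arm cohort of ``3 * n_per_arm`` patients.

    Enrollment proceeds until every arm reaches ``n_per_arm`` (stratified
    permuted blocks make overshoot minimal); labs are censored at death.
    Deterministic for a fixed ``config.seed``.
    """
    n_target = 3 * config.n_per_arm
    rng_cov = _rng(config, "covariates")
    rng_events = _rng(config, "events")
    rng_scr = _rng(config, "scr")
    rng_vitd = _rng(config, "vitd")
    rng_min = _rng(config, "minerals")
    rng_uop = _rng(config, "uop")

    # draw a surplus of candidates, randomize, then enroll the first
    # n_per_arm in each arm so totals are exact
    n_draw = n_target + 12
    covs = _draw_covariates(n_draw, config, rng_cov)
    arms = assign_randomization([c["aki_on_enrollment"] for c in covs], seed=config.seed)

    patients: List[PatientRecord] = []
    per_arm = {arm: 0 for arm in ARMS}
    for i, (cov, arm) in enumerate(zip(covs, arms)):
        if per_arm[arm] >= config.n_per_arm:
            continue
        per_arm[arm] += 1
        baseline_25d = cov.pop("baseline_25d")
        baseline_125d = cov.pop("baseline_125d")
        p = PatientRecord(id=f"P{i + 1:04d}", arm=arm, **cov)
        simulate_events(p, config, rng_events)
        scr = simulate_scr_trajectory(p, config, rng_scr)
        s25, s125 = simulate_vitd_pk(
            arm, baseline_25d, baseline_125d, config, rng_vitd, death_day=p.death_day
        )
        ca, po4 = simulate_mineral_labs(p, config, rng_min)
        uop = simulate_uop(p, config, rng_uop)
        p.labs = {"scr": scr, "25d": s25, "125d": s125, "calcium": ca, "phosphate": po4,
                  "uop": uop}
        patients.append(p)
        if len(patients) == n_target and all(v >= config.n_per_arm for v in per_arm.values()):
            break
    if len(patients) < n_target:
        raise RuntimeError("candidate surplus exhausted before filling all arms")
    return patients
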