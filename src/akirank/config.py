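"""Configuration models for the synthetic cohort generator and trial design.

Defaults encode the study conditions the analysis assumes: a three-arm
(calcifediol / calcitriol / placebo) critically-ill cohort with ~35% AKI
prevalence at enrollment, arm-specific 7-day death and KRT risks, skewed
baseline vitamin D metabolite levels, and per-arm pharmacokinetic
fold-change schedules for 25-hydroxyvitamin D (25D) and
1,25-dihydroxyvitamin D (1,25D).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

ARMS = ("calcifediol", "calcitriol", "placebo")
ACTIVE_ARMS = ("calcifediol", "calcitriol")
PLACEBO = "placebo"


def lognormal_from_median_iqr(median: float, q25: float, q75: float) -> Dict[str, float]:
    """Solve lognormal (mu, sigma) from a printed median and IQR.

    mu = ln(median); sigma chosen so the theoretical quartile ratio matches
    the printed one: sigma = ln(q75/q25) / (2 * z_0.75), z_0.75 ≈ 0.67449.
    """
    z75 = 0.6744897501960817
    return {"mu": math.log(median), "sigma": math.log(q75 / q25) / (2.0 * z75)}


class ScrModel(BaseModel):
    """Latent-drift model for serum creatinine trajectories.

    Each patient draws a trajectory state (improving / stable / worsening),
    a daily multiplicative drift for that state (%/day, jittered per
    patient), and i.i.d. multiplicative lognormal daily noise. Day 0 is the
    enrollment (baseline) value exactly.
    """

    state_probs: Dict[str, float] = Field(
        default={"improving": 0.35, "stable": 0.35, "worsening": 0.30}
    )
    drift_by_state: Dict[str, float] = Field(
        default={"improving": -7.0, "stable": 0.0, "worsening": 6.0},
        description="latent drift, % per day",
    )
    drift_jitter_sd: float = Field(default=2.0, description="per-patient drift jitter, %/day")
    noise_sd: float = Field(default=8.0, description="daily multiplicative noise, % of value")

    @model_validator(mode="after")
    def _check(self) -> "ScrModel":
        if set(self.state_probs) != set(self.drift_by_state):
            raise ValueError("state_probs and drift_by_state must share keys")
        total = sum(self.state_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1")
        if any(p < 0 for p in self.state_probs.values()):
            raise ValueError("state probabilities must be non-negative")
        if self.noise_sd < 0 or self.drift_jitter_sd < 0:
            raise ValueError("noise/jitter SDs must be non-negative")
        return self


class MineralModel(BaseModel):
    """Daily serum calcium / phosphate model (mg/dL).

    Patient-level means with additive arm offsets plus within-patient daily
    noise; calcitriol carries the largest offsets so hypercalcemia
    (> 10.7 mg/dL) stays rare and phosphate runs highest in that arm.
    """

    ca_mean: float = 8.6
    ca_between_sd: float = 0.45
    ca_within_sd: float = 0.25
    ca_arm_offset: Dict[str, float] = Field(
        default={"calcifediol": 0.15, "calcitriol": 0.40, "placebo": 0.0}
    )
    po4_mean: float = 3.8
    po4_between_sd: float = 0.85
    po4_within_sd: float = 0.30
    po4_arm_offset: Dict[str, float] = Field(
        default={"calcifediol": 0.30, "calcitriol": 1.00, "placebo": 0.0}
    )


class UopModel(BaseModel):
    """Hourly urine output model (mL/kg/h): lognormal patient level times
    lognormal hourly noise; levels below 0.5 produce oliguric runs."""

    log_mean: float = 0.0  # median 1.0 mL/kg/h
    log_sd: float = 0.45
    hourly_noise_sd: float = 0.25  # lognormal sigma


# Per-arm deterministic fold-change schedules for days 0..7 (day 0 == 1.0).
# Calcifediol doubles 25D by day 1 and reaches 3-fold by day 5 (dosing ends
# day 4; levels plateau); its 1,25D rises modestly (1.5-fold by day 2).
# Calcitriol raises 1,25D 2.5-fold by day 2 and leaves 25D flat. Placebo flat.
DEFAULT_PK_MULTIPLIERS: Dict[str, Dict[str, List[float]]] = {
    "calcifediol": {
        "25d": [1.0, 2.0, 2.25, 2.5, 2.75, 3.0, 3.0, 3.0],
        "125d": [1.0, 1.25, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5],
    },
    "calcitriol": {
        "25d": [1.0] * 8,
        "125d": [1.0, 1.75, 2.5, 2.5, 2.5, 2.5, 2.5, 2.5],
    },
    "placebo": {"25d": [1.0] * 8, "125d": [1.0] * 8},
}


class CohortConfig(BaseModel):
    """Full configuration of the synthetic three-arm ICU cohort."""

    n_per_arm: int = Field(default=50, ge=1)
    seed: int = 0
    horizon_days: int = Field(default=7, ge=7)
    followup_days: int = 28

    aki_prevalence: float = Field(default=0.35, ge=0.0, le=1.0)
    death_risk_7d_by_arm: Dict[str, float] = Field(
        default={"calcifediol": 0.078, "calcitriol": 0.180, "placebo": 0.122}
    )
    krt_risk_7d_by_arm: Dict[str, float] = Field(
        default={"calcifediol": 0.020, "calcitriol": 0.020, "placebo": 0.082}
    )
    death_risk_28d_by_arm: Dict[str, float] = Field(
        default={"calcifediol": 0.16, "calcitriol": 0.30, "placebo": 0.24},
        description="cumulative 28-day mortality; must dominate the 7-day risk",
    )

    baseline_scr_log_mean: float = 0.0  # median 1.0 mg/dL
    baseline_scr_log_sd: float = 0.35
    scr: ScrModel = Field(default_factory=ScrModel)

    # lognormal baseline metabolite levels solved from median [IQR]:
    # 25D 16.1 [10.2-25.9] ng/mL; 1,25D 26.9 [17.5-39.1] pg/mL
    vitd_baseline_params: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {
            "25d": lognormal_from_median_iqr(16.1, 10.2, 25.9),
            "125d": lognormal_from_median_iqr(26.9, 17.5, 39.1),
        }
    )
    pk_multipliers: Dict[str, Dict[str, List[float]]] = Field(
        default_factory=lambda: {
            arm: {a: list(v) for a, v in d.items()} for arm, d in DEFAULT_PK_MULTIPLIERS.items()
        }
    )
    pk_noise_cv: float = Field(default=0.15, ge=0.0, description="lognormal CV of PK noise")

    minerals: MineralModel = Field(default_factory=MineralModel)
    uop: UopModel = Field(default_factory=UopModel)

    @field_validator("death_risk_7d_by_arm", "krt_risk_7d_by_arm", "death_risk_28d_by_arm")
    @classmethod
    def _check_probs(cls, v: Dict[str, float]) -> Dict[str, float]:
        for arm, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"risk for arm {arm!r} must be a probability, got {p}")
        missing = set(ARMS) - set(v)
        if missing:
            raise ValueError(f"missing arms in risk map: {sorted(missing)}")
        return v

    @model_validator(mode="after")
    def _check_pk(self) -> "CohortConfig":
        for arm, sched in self.pk_multipliers.items():
            for analyte, mults in sched.items():
                if not mults or abs(mults[0] - 1.0) > 1e-12:
                    raise ValueError(
                        f"pk multiplier at day 0 must be 1.0 for {arm}/{analyte}"
                    )
                if any(m <= 0 for m in mults):
                    raise ValueError(f"pk multipliers must be positive for {arm}/{analyte}")
        for arm in ARMS:
            d7, d28 = self.death_risk_7d_by_arm[arm], self.death_risk_28d_by_arm[arm]
            if d28 < d7:
                raise ValueError(f"28-day death risk below 7-day risk for arm {arm!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


class TrialDesign(BaseModel):
    """Two-sample design for one active-vs-placebo contrast.

    alpha is split by design (0.025 two-sided per contrast for two active
    arms); the effect is expressed in SD units of the continuous endpoint.
    """

    n_per_group: int = Field(default=50, ge=2)
    delta_sd: float = Field(default=0.62, ge=0.0)
    alpha_two_sided: float = Field(default=0.025, gt=0.0, lt=1.0)
    n_active_arms: int = Field(default=2, ge=1)


DEFAULT_COHORT = CohortConfig()


def load_config(path: Optional[str]) -> CohortConfig:
    return CohortConfig.from_yaml(path) if path else CohortConfig()
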