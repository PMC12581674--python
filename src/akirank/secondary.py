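"""Secondary endpoints, safety flags, and supporting statistics.

Covers the event-free-days construction (death before day 28 scores zero),
new-or-progressive AKI, KRT-or-death, peak creatinine, hypercalcemia /
hyperphosphatemia flags (strict thresholds), Fisher / chi-square contrasts
for binary endpoints, a repeated-measures mixed model for longitudinal
labs, multiple imputation with Rubin's-rules pooling, daily SOFA scoring
from a configurable cutoff grid, and urinary biomarker normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ACTIVE_ARMS, ARMS, PLACEBO
from .global_rank import build_rank_input
from .kdigo import stage_trajectory
from .records import HOURS_PER_DAY, LabSeries, PatientRecord

__all__ = [
    "free_days",
    "new_or_progressive_aki",
    "krt_or_death",
    "peak_scr",
    "SafetyFlags",
    "safety_flags",
    "compare_binary",
    "longitudinal_compare",
    "mice_pool",
    "sofa_daily",
    "normalize_kim1",
    "vitamin_d_status",
    "outcome_table",
]

HYPERCALCEMIA_THRESHOLD = 10.7  # mg/dL, strict >
HYPERPHOSPHATEMIA_THRESHOLD = 6.0  # mg/dL, strict >


def free_days(stay_days: int, death_day: Optional[int], horizon: int = 28) -> int:
    """Event-free days: ``horizon - stay`` for survivors (floored at zero);
    death before the horizon scores exactly zero (competing risk)."""
    if stay_days < 0:
        raise ValueError("stay_days must be non-negative")
    if death_day is not None and death_day < horizon:
        return 0
    return max(0, horizon - int(stay_days))


def new_or_progressive_aki(patient: PatientRecord, enrollment_stage: int,
                           horizon_days: int = 7) -> bool:
    """True iff the maximum KDIGO stage on days 1..horizon exceeds the
    enrollment stage."""
    times = [d * HOURS_PER_DAY for d in range(1, horizon_days + 1)]
    stages = [a.stage for a in stage_trajectory(patient, times)]
    return max(stages, default=0) > enrollment_stage


def krt_or_death(patient: PatientRecord) -> bool:
    return patient.died_7d or patient.krt_7d


def peak_scr(scr: LabSeries, horizon_days: int = 7) -> float:
    """Peak creatinine over day bins 0..horizon."""
    mask = scr.times_h < HOURS_PER_DAY * (horizon_days + 1)
    if not mask.any():
        raise ValueError("no observations within horizon")
    return float(scr.values[mask].max())


@dataclass(frozen=True)
class SafetyFlags:
    hypercalcemia: bool
    hyperphosphatemia: bool
    peak_calcium: float
    peak_calcium_day: int
    peak_phosphate: float
    peak_phosphate_day: int


def safety_flags(ca: LabSeries, po4: LabSeries, horizon_days: int = 7) -> SafetyFlags:
    """Hypercalcemia (> 10.7 mg/dL) and hyperphosphatemia (> 6.0 mg/dL)
    within the first ``horizon_days``; thresholds are strict, so boundary
    values do not flag."""
    def peak(series: LabSeries) -> Tuple[float, int]:
        mask = series.times_h < HOURS_PER_DAY * (horizon_days + 1)
        if not mask.any():
            raise ValueError(f"{series.analyte}: no observations within horizon")
        vals, times = series.values[mask], series.times_h[mask]
        i = int(np.argmax(vals))
        return float(vals[i]), int(times[i] // HOURS_PER_DAY)

    ca_peak, ca_day = peak(ca)
    po4_peak, po4_day = peak(po4)
    return SafetyFlags(
        hypercalcemia=ca_peak > HYPERCALCEMIA_THRESHOLD,
        hyperphosphatemia=po4_peak > HYPERPHOSPHATEMIA_THRESHOLD,
        peak_calcium=ca_peak, peak_calcium_day=ca_day,
        peak_phosphate=po4_peak, peak_phosphate_day=po4_day,
    )


def compare_binary(a_events: int, a_n: int, b_events: int, b_n: int,
                   method: str = "fisher",
                   chi2_correction: bool = False) -> float:
    """Two-sided p for a 2x2 contrast of event counts.

    ``fisher`` uses the exact point-probability method (sum of
    hypergeometric probabilities no larger than the observed table's);
    ``chi2`` is the 1-df chi-square test, without continuity correction by
    default.
    """
    if a_n <= 0 or b_n <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= a_events <= a_n and 0 <= b_events <= b_n):
        raise ValueError("event counts must lie within group sizes")
    table = np.array([[a_events, a_n - a_events], [b_events, b_n - b_events]])
    if method == "fisher":
        return _fisher_exact_two_sided(table)
    if method == "chi2":
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return 1.0
        _, p, _, _ = stats.chi2_contingency(table, correction=chi2_correction)
        return float(p)
    raise ValueError(f"unknown method {method!r}")


def _fisher_exact_two_sided(table: np.ndarray) -> float:
    """Point-probability two-sided Fisher test on a 2x2 table."""
    a = int(table[0, 0])
    n1, n2 = int(table[0].sum()), int(table[1].sum())
    k = int(table[:, 0].sum())
    n = n1 + n2
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = stats.hypergeom.pmf(support, n, k, n1)
    p_obs = float(pmf[support == a][0])
    # relative tolerance guards against float noise on equal-probability tables
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


@dataclass(frozen=True)
class LongitudinalResult:
    p_value: Optional[float]
    estimable: bool
    coefficients: Optional[Dict[str, float]] = None
    note: str = ""


def longitudinal_compare(data: pd.DataFrame, value_col: str = "value",
                         time_col: str = "time", arm_col: str = "arm",
                         id_col: str = "patient_id") -> LongitudinalResult:
    """Repeated-measures comparison of a longitudinal lab between arms.

    Fits a linear mixed model with a random intercept per patient and fixed
    effects for arm, time, and arm x time, then returns the joint Wald p
    for the arm main effect. A numerically zero arm contrast returns p = 1
    (no evidence of separation); singular or non-convergent fits return a
    not-estimable marker.
    """
    import statsmodels.formula.api as smf

    df = data[[id_col, arm_col, time_col, value_col]].dropna().copy()
    if df[arm_col].nunique() < 2 or len(df) < 4:
        return LongitudinalResult(None, False, note="insufficient groups or rows")
    formula = f"{value_col} ~ C({arm_col}) * {time_col}"
    try:
        with np.errstate(all="ignore"):
            model = smf.mixedlm(formula, df, groups=df[id_col])
            fit = model.fit(reml=False, method="lbfgs", disp=False)
        names = [n for n in fit.fe_params.index if n.startswith(f"C({arm_col})") and ":" not in n]
        beta = fit.fe_params[names].to_numpy()
        if np.max(np.abs(beta)) < 1e-10:
            return LongitudinalResult(1.0, True, dict(fit.fe_params), "zero arm contrast")
        constraint = ", ".join(f"{n} = 0" for n in names)
        wald = fit.wald_test(constraint, scalar=True)
        p = float(wald.pvalue)
        if not np.isfinite(p):
            return LongitudinalResult(None, False, note="singular covariance")
        return LongitudinalResult(p, True, dict(fit.fe_params))
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as err:
        return LongitudinalResult(None, False, note=f"fit failed: {err}")


def rubin_pool(estimates: Sequence[np.ndarray], variances: Sequence[np.ndarray],
               n_obs: int, n_params: int) -> pd.DataFrame:
    """Rubin's rules: pool per-imputation estimates and squared SEs.

    Total variance T = W + (1 + 1/m) B with W the mean within-imputation
    variance and B the between-imputation variance; p-values use the
    classical Rubin degrees of freedom (infinite when B = 0).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.shape[0]
    qbar = q.mean(axis=0)
    w = u.mean(axis=0)
    b = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    t = w + (1.0 + 1.0 / m) * b
    se = np.sqrt(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b / w
        df = np.where(b > 0, (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
    stat = np.divide(qbar, se, out=np.zeros_like(qbar), where=se > 0)
    p = np.where(
        np.isinf(df),
        2.0 * stats.norm.sf(np.abs(stat)),
        2.0 * stats.t.sf(np.abs(stat), np.where(np.isinf(df), 1.0, df)),
    )
    p = np.where(se > 0, p, np.where(qbar == 0, 1.0, 0.0))
    return pd.DataFrame({"estimate": qbar, "se": se, "p_value": p, "df": df})


def mice_pool(data: pd.DataFrame, formula: str, m: int = 5,
              seed: int = 0) -> pd.DataFrame:
    """Chained-equations multiple imputation pooled by Rubin's rules.

    Fits an OLS model per completed dataset (statsmodels MICE provides the
    imputation engine) and pools coefficients with :func:`rubin_pool`.
    With no missing data the result equals the complete-data fit exactly.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.imputation.mice import MICEData

    if m < 1:
        raise ValueError("m must be >= 1")
    all_missing = [c for c in data.columns if data[c].isna().all()]
    if all_missing:
        raise ValueError(f"columns entirely missing: {all_missing}")

    if not data.isna().any().any():
        fit = smf.ols(formula, data).fit()
        out = rubin_pool([fit.params.to_numpy()], [fit.bse.to_numpy() ** 2],
                         len(data), len(fit.params))
        out.index = fit.params.index
        return out

    np.random.seed(seed)  # statsmodels MICE draws from the global RNG
    imp = MICEData(data)
    estimates, variances, index = [], [], None
    for _ in range(m):
        imp.update_all()
        fit = smf.ols(formula, imp.data).fit()
        estimates.append(fit.params.to_numpy())
        variances.append(fit.bse.to_numpy() ** 2)
        index = fit.params.index
    out = rubin_pool(estimates, variances, len(data), len(index))
    out.index = index
    return out


# --- SOFA scoring ----------------------------------------------------------

#: Standard six-organ SOFA grid. Each organ maps to ordered (bound, score)
#: pairs; "low" direction scores higher as the value falls, "high" as it
#: rises. The cardiovascular axis additionally accepts a direct category
#: 0-4 (vasopressor dose tiers) via the ``cardiovascular_category`` input.
DEFAULT_SOFA_TABLE: Dict[str, dict] = {
    "respiration_pf": {"direction": "low", "bounds": [(100, 4), (200, 3), (300, 2), (400, 1)]},
    "coagulation_platelets": {"direction": "low", "bounds": [(20, 4), (50, 3), (100, 2), (150, 1)]},
    "liver_bilirubin": {"direction": "high", "bounds": [(12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1)]},
    "cardiovascular_map": {"direction": "low", "bounds": [(70, 1)]},
    "cns_gcs": {"direction": "low", "bounds": [(6, 4), (9, 3), (12, 2), (14, 1)]},
    "renal_creatinine": {"direction": "high", "bounds": [(5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1)]},
}


def _sofa_subscore(value: float, spec: dict) -> int:
    if spec["direction"] == "low":
        for bound, score in spec["bounds"]:
            if value < bound:
                return score
        return 0
    for bound, score in spec["bounds"]:
        if value >= bound:
            return score
    return 0


def sofa_daily(organ_inputs: Dict[str, Optional[float]],
               score_table: Optional[Dict[str, dict]] = None
               ) -> Tuple[int, Tuple[str, ...]]:
    """Daily SOFA score (0-24) from six organ inputs.

    Missing organs score 0 and are returned as flags (common ICU-trial
    convention; carry-forward is the caller's alternative). A
    ``cardiovascular_category`` input (0-4) overrides the MAP-based
    cardiovascular subscore to represent vasopressor tiers.
    """
    table = score_table if score_table is not None else DEFAULT_SOFA_TABLE
    total = 0
    missing: List[str] = []
    cardio_cat = organ_inputs.get("cardiovascular_category")
    for organ, spec in table.items():
        if organ == "cardiovascular_map" and cardio_cat is not None:
            cat = int(cardio_cat)
            if not 0 <= cat <= 4:
                raise ValueError("cardiovascular_category must be 0-4")
            total += cat
            continue
        value = organ_inputs.get(organ)
        if value is None:
            missing.append(organ)
            continue
        sub = _sofa_subscore(float(value), spec)
        if not 0 <= sub <= 4:
            raise ValueError(f"{organ}: subscore out of range")
        total += sub
    return total, tuple(missing)


def normalize_kim1(urinary_kim1: float, urine_creatinine: float) -> float:
    """Urinary KIM-1 normalized to urinary creatinine (dilution control)."""
    if urine_creatinine <= 0:
        raise ValueError("urine creatinine must be positive")
    if urinary_kim1 < 0:
        raise ValueError("KIM-1 must be non-negative")
    return urinary_kim1 / urine_creatinine


def vitamin_d_status(levels_ng_ml: Sequence[float]) -> pd.Series:
    """Enrollment 25D status: counts and percentages below the 30 / 20 / 10
    ng/mL insufficiency, deficiency, and severe-deficiency cutpoints."""
    x = np.asarray([v for v in levels_ng_ml if v is not None and np.isfinite(v)], dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no measured levels")
    out = {"n": n}
    for name, cut in (("insufficient_lt30", 30.0), ("deficient_lt20", 20.0),
                      ("severe_lt10", 10.0)):
        k = int((x < cut).sum())
        out[f"{name}_count"] = k
        out[f"{name}_pct"] = round(100.0 * k / n, 1)
    return pd.Series(out)


# --- outcome table ---------------------------------------------------------

def _summ(values: Sequence[float]) -> str:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return "NA"
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} [{q1:.1f}, {q3:.1f}]"


def outcome_table(patients: Sequence[PatientRecord], horizon_days: int = 7,
                  followup_days: int = 28, binary_method: str = "fisher"
                  ) -> pd.DataFrame:
    """Per-arm secondary/safety endpoint summary with active-vs-placebo
    contrast p-values (Fisher by default for counts, rank-sum for
    continuous summaries)."""
    by_arm: Dict[str, List[PatientRecord]] = {arm: [] for arm in ARMS}
    for p in patients:
        by_arm.setdefault(p.arm, []).append(p)

    def arm_metrics(arm_patients: List[PatientRecord]) -> dict:
        n = len(arm_patients)
        deaths = sum(p.died_7d for p in arm_patients)
        krt = sum(p.krt_7d for p in arm_patients)
        npa = sum(
            new_or_progressive_aki(p, 1 if p.aki_on_enrollment else 0, horizon_days)
            for p in arm_patients
        )
        kod = sum(krt_or_death(p) for p in arm_patients)
        mort28 = sum(p.died_28d for p in arm_patients)
        peaks = [peak_scr(p.lab("scr"), horizon_days) for p in arm_patients if p.lab("scr")]
        icu_free = [free_days(p.icu_days, p.death_day, followup_days) for p in arm_patients]
        hosp_free = [free_days(p.hospital_days, p.death_day, followup_days)
                     for p in arm_patients]
        flags = [
            safety_flags(p.lab("calcium"), p.lab("phosphate"), horizon_days)
            for p in arm_patients if p.lab("calcium") and p.lab("phosphate")
        ]
        return dict(
            n=n, deaths_7d=deaths, krt_7d=krt, new_or_progressive_aki=npa,
            krt_or_death=kod, mortality_28d=mort28,
            peak_scr=peaks, icu_free_days=icu_free, hospital_free_days=hosp_free,
            hypercalcemia=sum(f.hypercalcemia for f in flags),
            hyperphosphatemia=sum(f.hyperphosphatemia for f in flags),
        )

    metrics = {arm: arm_metrics(by_arm[arm]) for arm in ARMS}

    binary_rows = ["deaths_7d", "krt_7d", "new_or_progressive_aki", "krt_or_death",
                   "mortality_28d", "hypercalcemia", "hyperphosphatemia"]
    continuous_rows = ["peak_scr", "icu_free_days", "hospital_free_days"]

    rows = []
    for endpoint in binary_rows + continuous_rows:
        row: Dict[str, object] = {"endpoint": endpoint}
        for arm in ARMS:
            m = metrics[arm]
            if endpoint in binary_rows:
                row[arm] = f"{m[endpoint]}/{m['n']}"
            else:
                row[arm] = _summ(m[endpoint])
        for active in ACTIVE_ARMS:
            a, b = metrics[active], metrics[PLACEBO]
            if endpoint in binary_rows:
                row[f"p_{active}"] = compare_binary(
                    int(a[endpoint]), a["n"], int(b[endpoint]), b["n"], binary_method
                )
                row["test"] = binary_method
            else:
                va, vb = np.asarray(a[endpoint], float), np.asarray(b[endpoint], float)
                if va.size and vb.size:
                    row[f"p_{active}"] = float(
                        stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
                    )
                else:
                    row[f"p_{active}"] = np.nan
                row["test"] = "wilcoxon"
        rows.append(row)
    return pd.DataFrame(rows)
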