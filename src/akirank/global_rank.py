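"""Hierarchical composite ("global rank") primary endpoint.

Patients are ordered by their worst outcome within 7 days of enrollment:
death is the worst tier, survival with kidney replacement therapy (KRT)
the next, and survivors without KRT are ordered by their baseline-adjusted
mean percent change in serum creatinine. Rank 1 is the best outcome; tied
patients (all deaths, all KRT, equal creatinine changes) share midranks.
Arms are compared with the Wilcoxon rank-sum test, exact by enumeration at
small pooled sizes and by a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import ACTIVE_ARMS, PLACEBO
from .records import HOURS_PER_DAY, LabSeries, PatientRecord

__all__ = [
    "GlobalRankInput",
    "RankedPatient",
    "ArmComparison",
    "baseline_adjusted_mean_change",
    "build_rank_input",
    "assign_global_ranks",
    "compare_arms",
    "subgroup_analysis",
]

TIER_SEVERITY = {"scr": 0, "krt": 1, "death": 2}
EXACT_THRESHOLD = 16  # pooled size at or below which the exact test is used


@dataclass(frozen=True)
class GlobalRankInput:
    """Per-patient endpoint input: event flags and, for event-free
    survivors, the baseline-adjusted mean SCr change (percent)."""

    patient_id: str
    died_7d: bool
    krt_7d: bool
    scr_mean_change: Optional[float] = None
    imputed_zero: bool = False  # survivor with no usable post-baseline SCr

    @property
    def tier(self) -> str:
        if self.died_7d:
            return "death"
        if self.krt_7d:
            return "krt"
        return "scr"

    def sort_key(self) -> Tuple[int, float]:
        sev = TIER_SEVERITY[self.tier]
        return (sev, self.scr_mean_change if sev == 0 else 0.0)


@dataclass(frozen=True)
class RankedPatient:
    patient_id: str
    tier: str
    rank: float  # midrank, 1 = best outcome


@dataclass(frozen=True)
class ArmComparison:
    """Two-sided rank-sum comparison of one arm against another."""

    statistic: float  # rank sum of the first group on the pooled ranking
    z: Optional[float]
    p_value: float
    method: str  # exact | normal_approx
    n_a: int
    n_b: int


def baseline_adjusted_mean_change(scr: LabSeries, baseline: float,
                                  horizon_days: int = 7,
                                  krt_start_day: Optional[int] = None
                                  ) -> Optional[float]:
    """Mean percent change from baseline over days 1..horizon.

    Averages ``100 * (SCr - baseline) / baseline`` over all observations in
    day bins 1..horizon, excluding values at or after KRT start. Returns
    ``None`` when no eligible observation exists (the caller decides how to
    treat such survivors; the analysis assigns 0% with a flag).
    """
    if baseline <= 0:
        raise ValueError("baseline creatinine must be positive")
    lo = HOURS_PER_DAY  # day 0 is the baseline itself
    hi = HOURS_PER_DAY * (horizon_days + 1)
    mask = (scr.times_h >= lo) & (scr.times_h < hi)
    if krt_start_day is not None:
        mask &= scr.times_h < krt_start_day * HOURS_PER_DAY
    if not mask.any():
        return None
    return float(np.mean(100.0 * (scr.values[mask] - baseline) / baseline))


def build_rank_input(patient: PatientRecord, horizon_days: int = 7) -> GlobalRankInput:
    """Derive the endpoint input for one patient from the record.

    Death takes precedence over KRT; event-free survivors with no usable
    post-baseline creatinine are assigned a 0% change and flagged
    (missing endpoint data are not imputed by a model).
    """
    died = patient.died_7d
    krt = patient.krt_7d and not died
    change: Optional[float] = None
    imputed = False
    if not died and not krt:
        scr = patient.lab("scr")
        if scr is not None:
            change = baseline_adjusted_mean_change(
                scr, patient.baseline_scr, horizon_days, patient.krt_start_day
            )
        if change is None:
            change, imputed = 0.0, True
    return GlobalRankInput(patient.id, died, krt, change, imputed)


def _midranks(keys: Sequence[Tuple[int, float]]) -> np.ndarray:
    """Midranks (1-based) of a total preorder given per-item sort keys."""
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = np.empty(len(keys), dtype=float)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and keys[order[j + 1]] == keys[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in order[i:j + 1]:
            ranks[k] = mid
        i = j + 1
    return ranks


def assign_global_ranks(inputs: Sequence[GlobalRankInput]) -> List[RankedPatient]:
    """Midranks over the death > KRT > SCr-change hierarchy (1 = best)."""
    ids = [x.patient_id for x in inputs]
    dup = [pid for pid, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate patient ids: {dup}")
    for x in inputs:
        if x.tier == "scr" and x.scr_mean_change is None:
            raise ValueError(f"{x.patient_id}: SCr-tier patient lacks a mean change")
    ranks = _midranks([x.sort_key() for x in inputs])
    return [RankedPatient(x.patient_id, x.tier, float(r)) for x, r in zip(inputs, ranks)]


def _rank_sum_pvalue_exact(pooled_ranks: np.ndarray, n_a: int) -> Tuple[float, float]:
    """Exact two-sided p by enumerating all group-A index subsets.

    Returns (rank sum of the observed first group, p). The observed group A
    occupies the first ``n_a`` positions of ``pooled_ranks``.
    """
    n = pooled_ranks.size
    w_obs = float(pooled_ranks[:n_a].sum())
    eps = 1e-9
    le = ge = total = 0
    for comb in itertools.combinations(range(n), n_a):
        w = float(pooled_ranks[list(comb)].sum())
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return w_obs, p


def _rank_sum_pvalue_normal(pooled_keys: Sequence[Tuple[int, float]],
                            pooled_ranks: np.ndarray, n_a: int
                            ) -> Tuple[float, float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n = pooled_ranks.size
    n_b = n - n_a
    w = float(pooled_ranks[:n_a].sum())
    mean = n_a * (n + 1) / 2.0
    tie_counts = Counter(pooled_keys).values()
    tie_term = sum(t**3 - t for t in tie_counts)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 0.0, 1.0
    delta = w - mean
    # 0.5 continuity correction toward the mean
    delta_cc = math.copysign(max(abs(delta) - 0.5, 0.0), delta)
    z = delta_cc / math.sqrt(var)
    return w, z, float(2.0 * stats.norm.sf(abs(z)))


def compare_arms(group_a: Sequence[GlobalRankInput],
                 group_b: Sequence[GlobalRankInput],
                 exact_threshold: int = EXACT_THRESHOLD) -> ArmComparison:
    """Wilcoxon rank-sum comparison of two arms on freshly pooled ranks.

    Ranks are recomputed on the pooled two-arm set. Exact enumeration is
    used when the pooled size is at most ``exact_threshold``; otherwise the
    tie-corrected normal approximation.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    pooled = list(group_a) + list(group_b)
    keys = [x.sort_key() for x in pooled]
    ranks = _midranks(keys)
    n_a = len(group_a)
    if len(pooled) <= exact_threshold:
        w, p = _rank_sum_pvalue_exact(ranks, n_a)
        return ArmComparison(w, None, p, "exact", n_a, len(group_b))
    w, z, p = _rank_sum_pvalue_normal(keys, ranks, n_a)
    return ArmComparison(w, z, p, "normal_approx", n_a, len(group_b))


# --- subgroup analyses -----------------------------------------------------

def default_subgroups(patients: Sequence[PatientRecord]) -> Dict[str, "callable"]:
    """The seven prespecified subgroup classifiers. Median splits (APACHE II,
    baseline 25D) are computed on the enrolled cohort passed in."""
    apache_med = float(np.median([p.apache2 for p in patients]))
    d25 = [
        p.lab("25d").value_on_day(0) for p in patients
        if p.lab("25d") is not None and p.lab("25d").value_on_day(0) is not None
    ]
    d25_med = float(np.median(d25)) if d25 else float("nan")
    return {
        "age": lambda p: "ge65" if p.age >= 65 else "lt65",
        "sex": lambda p: p.sex,
        "aki_on_enrollment": lambda p: "present" if p.aki_on_enrollment else "absent",
        "icu_type": lambda p: p.icu_type,
        "apache2": lambda p: "above_median" if p.apache2 > apache_med else "at_or_below_median",
        "septic_shock": lambda p: "present" if p.septic_shock else "absent",
        "baseline_25d": lambda p: (
            "above_median"
            if (p.lab("25d") is not None and (p.lab("25d").value_on_day(0) or 0.0) > d25_med)
            else "at_or_below_median"
        ),
    }


def subgroup_analysis(patients: Sequence[PatientRecord],
                      inputs: Optional[Dict[str, GlobalRankInput]] = None,
                      subgroups: Optional[Dict[str, "callable"]] = None,
                      horizon_days: int = 7):
    """Active-vs-placebo rank-sum comparisons within each subgroup level.

    Ranks are recomputed within each subgroup. Cells with an empty arm are
    reported as not estimable rather than raising. Returns a DataFrame with
    one row per (subgroup, level, contrast).
    """
    import pandas as pd

    if inputs is None:
        inputs = {p.id: build_rank_input(p, horizon_days) for p in patients}
    if subgroups is None:
        subgroups = default_subgroups(patients)

    rows = []
    for name, classify in subgroups.items():
        levels: Dict[str, List[PatientRecord]] = {}
        for p in patients:
            levels.setdefault(str(classify(p)), []).append(p)
        for level, members in sorted(levels.items()):
            by_arm: Dict[str, List[GlobalRankInput]] = {}
            for p in members:
                by_arm.setdefault(p.arm, []).append(inputs[p.id])
            for active in ACTIVE_ARMS:
                a, b = by_arm.get(active, []), by_arm.get(PLACEBO, [])
                row = dict(subgroup=name, level=level, contrast=f"{active}_vs_placebo",
                           n_active=len(a), n_placebo=len(b))
                if not a or not b:
                    row.update(p_value=np.nan, statistic=np.nan, method="not_estimable")
                else:
                    cmp_res = compare_arms(a, b)
                    row.update(p_value=cmp_res.p_value, statistic=cmp_res.statistic,
                               method=cmp_res.method)
                rows.append(row)
    return pd.DataFrame(rows)
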