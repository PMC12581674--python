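"""Two-sample power analysis: closed form and simulation.

The design question: with ``n`` patients per group and a standardized
effect ``delta`` (SD units) on a continuous endpoint, what is the power of
a two-sided level-``alpha`` comparison? The closed form is the normal
approximation ``power = Phi(delta * sqrt(n/2) - z_{1-alpha/2})`` (a
noncentral-t refinement is available); simulation supports the t-test, the
Wilcoxon rank-sum test, and the hierarchical global-rank endpoint with a
planted creatinine shift and optional event-rate shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .config import TrialDesign
from .global_rank import GlobalRankInput, compare_arms

__all__ = ["analytic_power", "simulate_power", "required_n", "PowerEstimate"]


def analytic_power(design: TrialDesign, use_noncentral_t: bool = False) -> float:
    """Power of the two-sided two-sample comparison under the design.

    Normal approximation by default: ``Phi(delta*sqrt(n/2) - z_{1-a/2})``
    plus the (negligible) opposite tail. ``use_noncentral_t`` switches to
    the exact noncentral-t power for the equal-variance t-test.
    """
    n, delta, alpha = design.n_per_group, design.delta_sd, design.alpha_two_sided
    nc = delta * math.sqrt(n / 2.0)
    if use_noncentral_t:
        df = 2 * n - 2
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(nc - zcrit) + stats.norm.cdf(-nc - zcrit))


def required_n(delta_sd: float, power_target: float, alpha_two_sided: float = 0.025,
               use_noncentral_t: bool = False) -> int:
    """Smallest per-group n whose analytic power reaches the target."""
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must be in (0, 1)")
    if delta_sd <= 0:
        if power_target <= alpha_two_sided:
            return 2
        raise ValueError("cannot reach power above alpha with zero effect")
    # closed-form start, then verify stepwise
    zc = stats.norm.ppf(1.0 - alpha_two_sided / 2.0)
    zp = stats.norm.ppf(power_target)
    n = max(2, int(math.floor(2.0 * ((zc + zp) / delta_sd) ** 2)) - 2)
    while n < 10_000_000:
        design = TrialDesign(n_per_group=n, delta_sd=delta_sd,
                             alpha_two_sided=alpha_two_sided)
        if analytic_power(design, use_noncentral_t) >= power_target:
            return n
        n += 1
    raise RuntimeError("required n exceeds search bound")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    reps: int
    test: str

    def within(self, target: float) -> bool:
        return self.ci_low <= target <= self.ci_high


def _simulate_global_rank_rep(rng: np.random.Generator, n: int, delta: float,
                              event_rates: Tuple[float, float, float, float],
                              alpha: float) -> bool:
    """One planted-effect trial: arm A carries a +delta SD creatinine shift
    and optionally shifted death/KRT risks."""
    pa_death, pa_krt, pb_death, pb_krt = event_rates

    def make_arm(prefix: str, n_arm: int, p_death: float, p_krt: float,
                 shift: float) -> list:
        u = rng.uniform(size=(n_arm, 2))
        changes = rng.normal(shift, 1.0, size=n_arm)
        out = []
        for i in range(n_arm):
            died = bool(u[i, 0] < p_death)
            krt = bool((not died) and u[i, 1] < p_krt)
            out.append(GlobalRankInput(
                f"{prefix}{i}", died, krt,
                None if (died or krt) else float(changes[i]),
            ))
        return out

    a = make_arm("a", n, pa_death, pa_krt, delta)
    b = make_arm("b", n, pb_death, pb_krt, 0.0)
    return compare_arms(a, b).p_value < alpha


def simulate_power(design: TrialDesign, test: str = "t", reps: int = 2000,
                   seed: int = 0,
                   event_rates: Optional[Dict[str, float]] = None) -> PowerEstimate:
    """Monte-Carlo power with a 95% binomial (normal) CI.

    ``test`` is one of ``t``, ``wilcoxon``, ``global_rank``. Data are
    normal with a location shift of ``delta_sd`` SDs in the first group;
    for ``global_rank`` the shift applies to the creatinine tier, with
    optional ``event_rates`` {death_a, krt_a, death_b, krt_b} (default 0).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    n, delta, alpha = design.n_per_group, design.delta_sd, design.alpha_two_sided

    if test in ("t", "wilcoxon"):
        x = rng.normal(delta, 1.0, size=(reps, n))
        y = rng.normal(0.0, 1.0, size=(reps, n))
        if test == "t":
            res = stats.ttest_ind(x, y, axis=1)
            hits = int((res.pvalue < alpha).sum())
        else:
            res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
            hits = int((res.pvalue < alpha).sum())
    elif test == "global_rank":
        er = event_rates or {}
        rates = (er.get("death_a", 0.0), er.get("krt_a", 0.0),
                 er.get("death_b", 0.0), er.get("krt_b", 0.0))
        hits = sum(
            _simulate_global_rank_rep(rng, n, delta, rates, alpha) for _ in range(reps)
        )
    else:
        raise ValueError(f"unknown test {test!r}")

    p = hits / reps
    half = 1.959963984540054 * math.sqrt(max(p * (1 - p), 1e-12) / reps)
    return PowerEstimate(p, max(0.0, p - half), min(1.0, p + half), reps, test)
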