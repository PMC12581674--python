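#!/usr/bin/env python
"""Power design: closed form, inversion, and simulation cross-checks.

Prints the analytic power at the design point (50/group, 0.62 SD,
alpha 0.025 two-sided), the smallest n achieving 80%, and Monte-Carlo
power for the t-test, the rank-sum test, and the global-rank composite
with a planted creatinine shift; writes results/power.json.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from akirank.config import TrialDesign
from akirank.power import analytic_power, required_n, simulate_power

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 20261001


def main() -> None:
    design = TrialDesign(n_per_group=50, delta_sd=0.62, alpha_two_sided=0.025)
    p_norm = analytic_power(design)
    p_nct = analytic_power(design, use_noncentral_t=True)
    n80 = required_n(0.62, 0.80, 0.025)
    print(f"analytic power (normal form): {p_norm:.3f} -> {100 * p_norm:.0f}%")
    print(f"analytic power (noncentral t): {p_nct:.3f}")
    print(f"smallest n/group for 80%: {n80}")

    out = {"analytic_normal": round(p_norm, 4),
           "analytic_noncentral_t": round(p_nct, 4),
           "required_n_80pct": n80, "simulated": {}}
    for test, reps in (("t", 4000), ("wilcoxon", 4000), ("global_rank", 1000)):
        est = simulate_power(design, test=test, reps=reps, seed=SEED,
                             event_rates={"death_a": 0.122, "krt_a": 0.082,
                                          "death_b": 0.122, "krt_b": 0.082})
        print(f"simulated power [{test}, {reps} reps]: {est.power:.3f} "
              f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")
        out["simulated"][test] = {"power": est.power, "ci_low": est.ci_low,
                                  "ci_high": est.ci_high, "reps": reps}

    os.makedirs(ROOT, exist_ok=True)
    with open(os.path.join(ROOT, "power.json"), "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    main()
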