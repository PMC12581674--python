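#!/usr/bin/env python
"""Primary hierarchical global-rank endpoint and subgroup analyses.

Reads results/cohort/, writes results/ranks.csv and results/subgroups.csv,
and prints each active-vs-placebo rank-sum comparison (the primary
threshold is two-sided p < 0.025 per contrast).
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np

from akirank.io import read_cohort
from akirank.pipeline import analyze

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cohort = read_cohort(os.path.join(ROOT, "cohort", "patients.csv"),
                         os.path.join(ROOT, "cohort", "labs.csv"))
    result = analyze(cohort, horizon_days=7)
    result["ranks"].to_csv(os.path.join(ROOT, "ranks.csv"), index=False)
    result["subgroups"].to_csv(os.path.join(ROOT, "subgroups.csv"), index=False)

    tiers = result["ranks"].tier.value_counts()
    print("endpoint tiers:", dict(tiers))
    for contrast, block in result["primary"].items():
        print(f"primary {contrast}: W={block['statistic']:.1f}, "
              f"p={block['p_value']:.3f} ({block['method']})")
    sub = result["subgroups"]
    est = sub[np.isfinite(sub.p_value)]
    print(f"subgroup comparisons: {len(est)} estimable of {len(sub)}; "
          f"smallest p = {est.p_value.min():.3f} "
          f"({est.loc[est.p_value.idxmin(), 'subgroup']}/"
          f"{est.loc[est.p_value.idxmin(), 'level']})")


if __name__ == "__main__":
    main()
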