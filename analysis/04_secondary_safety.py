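#!/usr/bin/env python
"""Secondary and safety endpoints plus the longitudinal mineral comparison.

Reads results/cohort/, writes results/outcomes.csv, and prints the per-arm
endpoint table with Fisher contrast p-values, then a repeated-measures
mixed-model comparison of serum calcium across arms.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from akirank.io import read_cohort
from akirank.secondary import longitudinal_compare, outcome_table

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cohort = read_cohort(os.path.join(ROOT, "cohort", "patients.csv"),
                         os.path.join(ROOT, "cohort", "labs.csv"))
    table = outcome_table(cohort)
    out = os.path.join(ROOT, "outcomes.csv")
    table.to_csv(out, index=False)
    print(f"outcome table -> {out}")
    with pd.option_context("display.width", 140):
        print(table.to_string(index=False))

    rows = []
    for p in cohort:
        ca = p.lab("calcium")
        for t, v in zip(ca.times_h, ca.values):
            rows.append({"patient_id": p.id, "arm": p.arm,
                         "time": t / 24.0, "value": v})
    res = longitudinal_compare(pd.DataFrame(rows))
    print(f"longitudinal calcium arm effect: p={res.p_value:.4g} "
          f"(estimable={res.estimable})")


if __name__ == "__main__":
    main()
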