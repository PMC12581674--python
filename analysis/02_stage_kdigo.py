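#!/usr/bin/env python
"""Stage AKI daily for the simulated cohort.

Reads results/cohort/, writes results/stages.csv, and prints the
distribution of each patient's worst KDIGO stage over the 7-day window.
"""

import os
import sys
from collections import Counter

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from akirank.io import read_cohort
from akirank.pipeline import stages_frame

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cohort = read_cohort(os.path.join(ROOT, "cohort", "patients.csv"),
                         os.path.join(ROOT, "cohort", "labs.csv"))
    stages = stages_frame(cohort, horizon_days=7)
    out = os.path.join(ROOT, "stages.csv")
    stages.to_csv(out, index=False)

    worst = stages.groupby("patient_id")["stage"].max()
    dist = Counter(worst)
    print(f"staged {len(cohort)} patients -> {out}")
    for stage in sorted(dist):
        print(f"  worst stage {stage}: {dist[stage]} patients")
    triggers = Counter(stages.loc[stages.stage > 0, "trigger"])
    print("triggers among staged rows:", dict(triggers))


if __name__ == "__main__":
    main()
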