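#!/usr/bin/env python
"""Simulate the trial-scale cohort (50 patients/arm) and summarize it.

Writes patients.csv / labs.csv under results/cohort/ and prints enrollment
descriptives: arm sizes, AKI prevalence, and vitamin D status at
enrollment (fractions below the 30/20/10 ng/mL cutpoints).
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np

from akirank.config import ARMS, CohortConfig
from akirank.cohort import generate_cohort
from akirank.io import write_cohort
from akirank.secondary import vitamin_d_status

SEED = 20261001
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")


def main() -> None:
    cfg = CohortConfig(n_per_arm=50, seed=SEED)
    patients = generate_cohort(cfg)
    paths = write_cohort(patients, OUT)

    print(f"simulated {len(patients)} patients -> {paths['patients']}")
    for arm in ARMS:
        print(f"  {arm}: {sum(p.arm == arm for p in patients)}")
    prev = np.mean([p.aki_on_enrollment for p in patients])
    print(f"AKI on enrollment: {100 * prev:.1f}%")

    d25 = [p.lab('25d').value_on_day(0) for p in patients]
    status = vitamin_d_status(d25)
    print(f"25D status at enrollment (n={int(status['n'])}): "
          f"{status['insufficient_lt30_pct']}% < 30, "
          f"{status['deficient_lt20_pct']}% < 20, "
          f"{status['severe_lt10_pct']}% < 10 ng/mL")
    med = np.median(d25)
    q1, q3 = np.percentile(d25, [25, 75])
    print(f"25D median [IQR]: {med:.1f} [{q1:.1f}-{q3:.1f}] ng/mL")


if __name__ == "__main__":
    main()
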