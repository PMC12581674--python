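"""End-to-end orchestration: simulate (or ingest) -> KDIGO staging ->
primary global-rank analysis -> secondary/safety endpoints -> report.

Every run writes CSV/JSON outputs plus a manifest (config hash, seed,
output hashes) so that re-running the same configuration reproduces the
analysis outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .config import ACTIVE_ARMS, PLACEBO, CohortConfig
from .cohort import generate_cohort
from .global_rank import assign_global_ranks, build_rank_input, compare_arms, subgroup_analysis
from .io import labs_frame, patients_frame, read_cohort, write_cohort
from .kdigo import ScreeningDecision, stage_trajectory
from .records import HOURS_PER_DAY, PatientRecord
from .secondary import outcome_table

log = logging.getLogger("akirank")

__all__ = ["run_pipeline", "consort_counts", "RunManifest", "stages_frame"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamp: Optional[str] = None  # excluded from determinism comparisons

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "outputs": self.outputs,
             "timestamp": self.timestamp},
            indent=2, sort_keys=True,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def stages_frame(patients: Sequence[PatientRecord], horizon_days: int = 7) -> pd.DataFrame:
    """Daily KDIGO assessments, one row per patient-day."""
    rows = []
    for p in patients:
        times = [d * HOURS_PER_DAY for d in range(0, horizon_days + 1)]
        if p.death_day is not None:
            times = [t for t in times if t <= p.death_day * HOURS_PER_DAY]
        for a in stage_trajectory(p, times):
            rows.append({"patient_id": p.id, "time_h": a.time_h,
                         "stage": a.stage, "trigger": a.trigger})
    return pd.DataFrame(rows, columns=["patient_id", "time_h", "stage", "trigger"])


def analyze(patients: Sequence[PatientRecord], horizon_days: int = 7) -> dict:
    """Primary + subgroup + secondary analyses on an in-memory cohort."""
    inputs = {p.id: build_rank_input(p, horizon_days) for p in patients}
    ranked = assign_global_ranks(list(inputs.values()))
    by_arm: Dict[str, list] = {}
    for p in patients:
        by_arm.setdefault(p.arm, []).append(inputs[p.id])

    n_imputed = sum(x.imputed_zero for x in inputs.values())
    if n_imputed:
        log.warning("%d survivors had no usable post-baseline SCr; "
                    "assigned 0%% change (flagged)", n_imputed)

    primary = {}
    for active in ACTIVE_ARMS:
        if by_arm.get(active) and by_arm.get(PLACEBO):
            c = compare_arms(by_arm[active], by_arm[PLACEBO])
            primary[f"{active}_vs_placebo"] = {
                "p_value": c.p_value, "statistic": c.statistic, "z": c.z,
                "method": c.method, "n_active": c.n_a, "n_placebo": c.n_b,
            }
        else:
            primary[f"{active}_vs_placebo"] = {"p_value": None, "method": "not_estimable"}

    ranks_df = pd.DataFrame(
        [{"patient_id": r.patient_id, "tier": r.tier, "rank": r.rank,
          "flag_imputed_zero": int(inputs[r.patient_id].imputed_zero)}
         for r in ranked]
    )
    subgroups_df = subgroup_analysis(list(patients), inputs)
    outcomes_df = outcome_table(list(patients), horizon_days)
    return {"primary": primary, "ranks": ranks_df, "subgroups": subgroups_df,
            "outcomes": outcomes_df, "n_imputed_zero": n_imputed}


def run_pipeline(config: CohortConfig, out_dir: str,
                 patients_path: Optional[str] = None,
                 labs_path: Optional[str] = None) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    With ``patients_path``/``labs_path`` the cohort is ingested from disk
    (validated); otherwise it is simulated from ``config``. The two paths
    produce identical analyses on identical data.
    """
    os.makedirs(out_dir, exist_ok=True)
    if patients_path and labs_path:
        patients = read_cohort(patients_path, labs_path)
        log.info("ingested %d patients from %s", len(patients), patients_path)
    else:
        patients = generate_cohort(config)
        log.info("simulated %d patients (seed %d)", len(patients), config.seed)

    paths = write_cohort(patients, out_dir)
    stages = stages_frame(patients, config.horizon_days)
    stage_path = os.path.join(out_dir, "stages.csv")
    stages.to_csv(stage_path, index=False)
    paths["stages"] = stage_path

    result = analyze(patients, config.horizon_days)
    ranks_path = os.path.join(out_dir, "ranks.csv")
    result["ranks"].to_csv(ranks_path, index=False)
    paths["ranks"] = ranks_path
    subg_path = os.path.join(out_dir, "subgroups.csv")
    result["subgroups"].to_csv(subg_path, index=False)
    paths["subgroups"] = subg_path
    out_path = os.path.join(out_dir, "outcomes.csv")
    result["outcomes"].to_csv(out_path, index=False)
    paths["outcomes"] = out_path

    arm_sizes = {arm: sum(p.arm == arm for p in patients)
                 for arm in sorted({p.arm for p in patients})}
    results_json = {
        "seed": config.seed,
        "n_patients": len(patients),
        "arm_sizes": arm_sizes,
        "primary": result["primary"],
        "n_imputed_zero": result["n_imputed_zero"],
    }
    results_path = os.path.join(out_dir, "results.json")
    with open(results_path, "w") as fh:
        json.dump(results_json, fh, indent=2, sort_keys=True)
    paths["results"] = results_path

    manifest = RunManifest(
        config_hash=config_hash(config), seed=config.seed, version=__version__,
        outputs={os.path.basename(v): _sha256(v) for v in paths.values()},
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def consort_counts(decisions: Sequence[ScreeningDecision],
                   randomized_arms: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """CONSORT-style tallies from a screening log.

    Counts screened / eligible (include) / excluded / unscreenable, one
    exclusion tally per reason code, and randomized-per-arm counts when arm
    labels for the included patients are provided.
    """
    rows = [{"category": "screened", "count": len(decisions)}]
    for kind in ("include", "exclude", "unscreenable"):
        rows.append({"category": kind,
                     "count": sum(d.decision == kind for d in decisions)})
    reason_counts: Dict[str, int] = {}
    for d in decisions:
        for r in d.reasons:
            reason_counts[r] = reason_counts.get(r, 0) + 1
    for reason in sorted(reason_counts):
        rows.append({"category": f"reason:{reason}", "count": reason_counts[reason]})
    if randomized_arms is not None:
        for arm in sorted(set(randomized_arms)):
            rows.append({"category": f"randomized:{arm}",
                         "count": sum(a == arm for a in randomized_arms)})
    return pd.DataFrame(rows)
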