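"""End-to-end orchestration: ingest -> derive PoDs -> MoE -> classify -> report.

Produces a tidy report bundle (CSV tables plus a run log) from an aggregated
biomonitoring percentile table and an assessment configuration.  Runs are
deterministic given config and seed; the run log embeds a hash of the
resolved configuration so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .config import AssessmentConfig, load_config, load_default_config
from .dosimetry import ENDPOINT_ABBREV, Endpoint, Population, hbm_pod
from .hbm import HBMRecord, Tier, read_hbm_csv, validate_records
from .risk import (
    ENDPOINT_CATEGORY,
    MoEResult,
    default_threshold_scheme,
    moe_for_record,
    moe_range,
    summarize_study,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

#: endpoints carried into the study reports (those with per-category cutoffs
#: exercised in the published roll-up)
REPORT_ENDPOINTS = (
    Endpoint.overall,
    Endpoint.long_term,
    Endpoint.short_term_ache,
    Endpoint.carcinogenicity,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    hbm_csv: Path
    config_yaml: Optional[Path] = None
    out_dir: Path
    pesticide: str = "chlorpyrifos"
    seed: int = 0


def _config_hash(cfg: AssessmentConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(run: RunConfig) -> dict[str, Path]:
    """Execute the full assessment and write the report bundle.

    Outputs (all CSV under ``run.out_dir``): ``hbm_pods.csv`` (endpoint x
    population biomonitoring-equivalent PoDs), ``moe_tidy.csv`` (one row per
    study x tier x endpoint with colour), ``moe_ranges.csv`` (min/max MoE per
    population group, endpoint and tier), ``study_rollup.csv`` (worst colour
    per study and tier with endpoint labels), and ``run_log.txt``.
    Returns the mapping of output name to path.
    """
    cfg = load_config(run.config_yaml) if run.config_yaml else load_default_config()
    scheme = cfg.thresholds or default_threshold_scheme()
    if run.pesticide not in cfg.pods:
        raise PipelineError("config", f"no PoD set for pesticide {run.pesticide!r}")

    raw = read_hbm_csv(run.hbm_csv)
    records, log = validate_records(raw)
    usable = [
        r for r in records if any(r.usable_for(t) for t in Tier)
    ]
    if not usable:
        raise PipelineError("ingest", f"no usable records in {run.hbm_csv}")

    pods = cfg.pods[run.pesticide]
    pods_by_pop = {
        pop: {p.endpoint: hbm_pod(p, cfg.toxicokinetics, pop) for p in pods}
        for pop in Population
    }

    # Table-1 style PoD report
    pod_rows = [
        dict(
            endpoint=p.endpoint.value,
            basis=p.basis.value,
            pod_mg_kg_day=p.value,
            hbm_pod_adults_mg_l=pods_by_pop[Population.adults][p.endpoint].reported_mg_l,
            hbm_pod_children_mg_l=pods_by_pop[Population.children][p.endpoint].reported_mg_l,
        )
        for p in pods
    ]

    # per-record MoEs with the population-matched PoD basis
    tidy: list[MoEResult] = []
    rollup_rows = []
    for rec in usable:
        pop = Population.children if rec.population == "children" else Population.adults
        hbm_pods = {
            e: pods_by_pop[pop][e]
            for e in REPORT_ENDPOINTS
            if e in pods_by_pop[pop]
        }
        results = moe_for_record(rec, hbm_pods, scheme)
        tidy.extend(results)
        if results:
            for tier, (color, label) in summarize_study(results).items():
                rollup_rows.append(
                    dict(
                        study_id=rec.study_id,
                        country=rec.country,
                        population=rec.population,
                        tier=tier.value,
                        worst_color=color.value,
                        endpoints=label,
                    )
                )

    tidy_rows = [
        dict(
            study_id=r.study_id,
            endpoint=r.endpoint.value,
            tier=r.tier.value,
            moe=r.reported_moe,
            color=r.color.value,
        )
        for r in tidy
    ]

    # Table-3 style ranges per population group
    range_rows = []
    for pop_label in sorted({r.population for r in usable}):
        group = [r for r in usable if r.population == pop_label]
        pop = Population.children if pop_label == "children" else Population.adults
        for endpoint in REPORT_ENDPOINTS:
            if endpoint not in pods_by_pop[pop]:
                continue
            for tier in (Tier.p50, Tier.p95, Tier.upper_ci):
                try:
                    lo, hi, contributors = moe_range(
                        group, endpoint, tier, pods_by_pop[pop]
                    )
                except ValueError:
                    continue
                range_rows.append(
                    dict(
                        population=pop_label,
                        endpoint=endpoint.value,
                        abbrev=ENDPOINT_ABBREV[endpoint],
                        tier=tier.value,
                        moe_min=round(lo),
                        moe_max=round(hi),
                        n_studies=len(contributors),
                    )
                )

    run.out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for name, rows in [
        ("hbm_pods", pod_rows),
        ("moe_tidy", tidy_rows),
        ("moe_ranges", range_rows),
        ("study_rollup", rollup_rows),
    ]:
        path = run.out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs[name] = path

    log_path = run.out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"biomoe {__version__} (python {sys.version.split()[0]})\n")
        fh.write(f"config_hash: {_config_hash(cfg)}\n")
        fh.write(f"seed: {run.seed}\n")
        fh.write(f"input: {run.hbm_csv}\n")
        fh.write(f"records: {len(records)} read, {len(usable)} usable\n")
        for study, msg in log.issues:
            fh.write(f"issue: {study}: {msg}\n")
    outputs["run_log"] = log_path
    return outputs
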