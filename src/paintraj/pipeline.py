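"""End-to-end orchestration: simulate/load -> extract -> select k ->
describe -> transitions -> sensitivity, with one master seed fanned out
to per-stage seeds by fixed offsets so every stage is individually
re-runnable from the recorded seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from . import describe as desc
from . import transitions as trans
from .cluster import ClusterSolution
from .datamodel import (Dataset, read_daily_csv, read_demographics_csv,
                        write_assignments, write_daily_csv,
                        write_demographics_csv, write_weeks_csv)
from .features import encode_weeks
from .selection import elbow_plot, select_k
from .sensitivity import run_sensitivity_1, run_sensitivity_2, run_sensitivity_3
from .synth import SyntheticConfig, generate_cohort
from .weeks import consecutive_pairs, extract_complete_weeks, weekday_index

logger = logging.getLogger(__name__)

STAGE_OFFSETS = {
    "simulate": 0,
    "cluster": 10_000,
    "sensitivity_1": 20_000,
    "sensitivity_2": 30_000,
    "sensitivity_3": 40_000,
    "bootstrap": 50_000,
}


@dataclass
class PipelineConfig:
    """Serialisable configuration of a full pipeline run."""

    master_seed: int = 0
    week_start_day: str = "mon"
    k_min: int = 1
    k_max: int = 20
    n_runs: int = 20
    threshold_pct: float = 5.0
    bootstrap_B: int = 1000
    bootstrap_level: float = 95.0
    force_k: Optional[int] = None
    run_sensitivity: bool = True
    daily_csv: Optional[str] = None
    demographics_csv: Optional[str] = None
    simulate: Optional[dict] = None  # SyntheticConfig overrides, or None

    def stage_seed(self, stage: str) -> int:
        return int(self.master_seed) + STAGE_OFFSETS[stage]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def synthetic_config_from_dict(d: Optional[dict], seed: int) -> SyntheticConfig:
    d = dict(d or {})
    if "study_start" in d and isinstance(d["study_start"], str):
        d["study_start"] = dt.date.fromisoformat(d["study_start"])
    for key in ("true_transition", "initial_state_probs"):
        if key in d and d[key] is not None:
            d[key] = np.asarray(d[key], dtype=float)
    if "state_levels" in d:
        d["state_levels"] = tuple(d["state_levels"])
    d.setdefault("seed", seed)
    return SyntheticConfig(**d)


def load_or_simulate(config: PipelineConfig, out_dir: Optional[Path] = None
                     ) -> Tuple[Dataset, Optional[object]]:
    """Return the input dataset, simulating one if no paths are configured."""
    if config.daily_csv is not None:
        if config.demographics_csv is None:
            raise ValueError("daily_csv given without demographics_csv")
        records = read_daily_csv(config.daily_csv)
        participants = read_demographics_csv(config.demographics_csv)
        ds = Dataset(records=records, participants=participants)
        ds.validate()
        return ds, None
    if config.simulate is None:
        raise ValueError("no input paths configured and simulation not requested")
    sc = synthetic_config_from_dict(config.simulate, config.stage_seed("simulate"))
    ds, truth = generate_cohort(sc)
    if out_dir is not None:
        write_daily_csv(ds.records, out_dir / "daily.csv")
        write_demographics_csv(ds.participants, out_dir / "demographics.csv")
        truth.frame().to_csv(out_dir / "ground_truth.csv", index=False)
    return ds, truth


def full_run(config: PipelineConfig, out_dir) -> dict:
    """Run the whole pipeline; write all stage outputs plus summary.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))

    dataset, _truth = load_or_simulate(config, out_dir)
    logger.info("input: %d records, %d participants",
                len(dataset.records), len(dataset.participants))

    wsd = weekday_index(config.week_start_day)
    weeks = extract_complete_weeks(dataset, week_start_day=wsd)
    logger.info("extracted %d complete participant weeks", len(weeks))
    if len(weeks) < config.k_max:
        raise ValueError(
            f"only {len(weeks)} complete weeks extracted; cannot scan k up to {config.k_max}"
        )
    write_weeks_csv(weeks, out_dir / "weeks.csv")

    X = encode_weeks(weeks, "ordinal7")
    report = select_k(
        X, k_range=(config.k_min, config.k_max), method="clara",
        metric="manhattan", threshold_pct=config.threshold_pct,
        n_runs=config.n_runs, base_seed=config.stage_seed("cluster"),
        force_k=config.force_k,
    )
    solution = report.solution
    letters = desc.assignment_letters(solution)
    write_assignments(weeks, letters, out_dir / "assignments.csv")
    (out_dir / "selection.json").write_text(json.dumps(report.summary(), indent=2))
    elbow_plot(report, out_dir / "elbow.png")

    profiles = desc.cluster_profiles(weeks, solution)
    for p in profiles:
        desc.spaghetti_plot(p, out_dir / f"cluster_{p.label}.png")
    shares = desc.cluster_shares(solution)

    proportions = desc.time_in_cluster(weeks, solution)
    summaries = desc.group_time_summaries(
        proportions, dataset.participants, B=config.bootstrap_B,
        level=config.bootstrap_level, seed=config.stage_seed("bootstrap"),
    )
    desc.summaries_frame(summaries).to_csv(out_dir / "time_in_cluster.csv", index=False)

    pairs = consecutive_pairs(weeks)
    amap = trans.assignment_map(weeks, letters)
    matrix = trans.transition_matrix(pairs, amap, labels=sorted(set(letters)))
    matrix.counts_frame().to_csv(out_dir / "transition_counts.csv")
    matrix.percentages_frame().to_csv(out_dir / "transition_percentages.csv")
    trans.transition_heatmap(matrix, out_dir / "transition_heatmap.png")
    stay, _per_row = trans.stay_percentage(matrix)

    summary = {
        "n_records": len(dataset.records),
        "n_participants": len(dataset.participants),
        "n_weeks": len(weeks),
        "n_pairs": len(pairs),
        "chosen_k": report.chosen_k,
        "elbow_k": report.elbow_k,
        "variability_explained_pct": report.variability_explained_pct,
        "cluster_shares_pct": {k: round(v, 2) for k, v in shares.items()},
        "overall_stay_pct": round(stay, 2),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGE_OFFSETS},
    }

    if config.run_sensitivity:
        s1 = run_sensitivity_1(weeks, solution,
                               base_seed=config.stage_seed("sensitivity_1"),
                               k_range=(config.k_min, config.k_max),
                               n_runs=config.n_runs,
                               threshold_pct=config.threshold_pct)
        s2 = run_sensitivity_2(weeks, solution,
                               base_seed=config.stage_seed("sensitivity_2"),
                               k_range=(config.k_min, config.k_max),
                               n_runs=config.n_runs,
                               threshold_pct=config.threshold_pct)
        s3 = run_sensitivity_3(dataset,
                               base_seed=config.stage_seed("sensitivity_3"),
                               k_range=(config.k_min, config.k_max),
                               n_runs=config.n_runs,
                               threshold_pct=config.threshold_pct)
        summary["sensitivity_1"] = s1.summary()
        summary["sensitivity_2"] = s2.summary()
        summary["sensitivity_3"] = {
            day: {
                "n_weeks": info["n_weeks"],
                "chosen_k": info["report"].chosen_k if info["report"] else None,
                "shares_pct": (
                    {k: round(v, 2) for k, v in info["shares"].items()}
                    if info["shares"] else None
                ),
            }
            for day, info in s3.items()
        }

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
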