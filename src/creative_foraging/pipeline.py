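"""End-to-end orchestration: enumerate, simulate or ingest, segment, analyze.

``run_pipeline`` drives the full analysis on one cohort — either logs read
from disk or a freshly simulated cohort — and writes a report bundle under
the configured output directory:

* ``logs.csv`` (+ ``truth.json`` when simulated)
* ``table1.csv`` — phase-characteristic medians with bootstrap CIs
* ``categories.json`` — category id -> shape strings
* ``patch_network.tsv`` — patch-id edge list of the overlap network
* ``cfg_scores.csv`` — per-player fluency/originality/composite
* ``metrics.json`` — every statistic the analysis computes, machine-readable

Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from . import category_analysis as ca
from . import phase_metrics as pm
from .game_log import read_logs, validate_log, write_logs
from .segmentation import segment
from .shape_space import MoveGraph
from .synthetic_data import SimParams, simulate_cohort

logger = logging.getLogger("creative_foraging")


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Either ``input_path`` (a cohort CSV/JSONL) or ``sim`` (simulation
    parameters) supplies the logs; simulation is the default.  ``n_boot``
    must stay >= 100 so bootstrap CIs remain meaningful.
    """

    n: int = 10
    seed: int = 0
    out_dir: str = "results/run"
    cache_dir: Optional[str] = None
    input_path: Optional[str] = None
    input_format: Optional[str] = None
    sim: SimParams = field(default_factory=SimParams)
    n_boot: int = 10_000
    k_values: Tuple[int, ...] = (1, 2, 3, 4, 5)
    max_pairs: Optional[int] = 20_000
    gn_patience: Optional[int] = None  # early dendrogram stop for big networks

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if isinstance(self.sim, dict):
            self.sim = SimParams(**self.sim)
        self.sim = replace(self.sim, n=self.n)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _stage(name: str, started: float) -> float:
    now = time.perf_counter()
    logger.info("%s: %.2fs", name, now - started)
    return now


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the whole analysis; returns the metrics dict it also writes.

    Aborts with ``ValueError`` and a per-player report if any input log
    violates the game rules (warnings are tolerated).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.cache_dir is not None:
        graph = MoveGraph.load_or_build(config.n, config.cache_dir)
    else:
        graph = MoveGraph.lazy(config.n)
    t0 = _stage("shape space ready", t0)

    truths = None
    if config.input_path is not None:
        logs = read_logs(config.input_path, fmt=config.input_format)
    else:
        logs, truths, categories_planted = simulate_cohort(
            graph, config.sim, seed=config.seed)
        write_logs(logs, out / "logs.csv")
        _dump_json([
            {"player_id": tr.player_id,
             "tempo_exploration": tr.tempo_exploration,
             "tempo_exploitation": tr.tempo_exploitation,
             "phases": [
                 {"kind": p.kind, "gallery_indices": [p.gallery_start, p.gallery_end],
                  "t_start": p.t_start, "t_end": p.t_end,
                  "transition_index": p.transition_index,
                  "category_id": p.category_id}
                 for p in tr.phases]}
            for tr in truths], out / "truth.json")
    t0 = _stage(f"{len(logs)} logs ready", t0)

    problems = []
    for log in logs:
        errors = [v for v in validate_log(log, graph) if v.severity == "error"]
        if errors:
            problems.append((log.player_id, errors))
    if problems:
        report = "; ".join(
            f"{pid}: " + ", ".join(f"[{v.event_index}] {v.rule}" for v in errs)
            for pid, errs in problems)
        raise ValueError(f"invalid logs: {report}")
    t0 = _stage("validation passed", t0)

    segmentations = [segment(log) for log in logs]
    _dump_json([s.to_dict() for s in segmentations], out / "segmentations.json")
    t0 = _stage("segmentation done", t0)

    rng = np.random.default_rng(config.seed)
    boot_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    metrics: Dict[str, object] = {
        "n_players": len(logs),
        "phase_pairs_per_player_median": float(np.median(
            [len(s.exploitation_phases()) for s in segmentations])),
        "moves_per_game_mean": float(np.mean([len(l.move_times()) for l in logs])),
        "saves_per_game_mean": float(np.mean(
            [len(l.gallery_shapes()) for l in logs])),
    }

    table1 = pm.phase_summary(segmentations, logs, n_boot=config.n_boot,
                              seed=boot_seed())
    table1.to_csv(out / "table1.csv")
    metrics["phase_summary"] = {
        stat: {"|".join(col): v for col, v in row.items() if v == v}
        for stat, row in table1.to_dict(orient="index").items()
    } if not table1.empty else {}
    t0 = _stage("phase summary done", t0)

    metrics["path_optimality"] = pm.path_ratio_summary(logs, segmentations, graph)
    t0 = _stage("path optimality done", t0)

    try:
        metrics["strategy_correlation"] = pm.strategy_correlation(
            segmentations, n_boot=config.n_boot, n_perm=config.n_boot,
            seed=boot_seed())
    except ValueError as exc:
        metrics["strategy_correlation"] = {"error": str(exc)}
    t0 = _stage("strategy correlation done", t0)

    patches = ca.extract_patches(segmentations, logs)
    network = ca.build_patch_network(patches)
    with open(out / "patch_network.tsv", "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a[0]}:{a[1]}\t{b[0]}:{b[1]}\n")
    partition = ca.detect_categories(network, patience=config.gn_patience)
    _dump_json({str(i): sorted(sh.to_string() for sh in cat)
                for i, cat in enumerate(partition.categories)},
               out / "categories.json")
    metrics["categories"] = {
        "n_categories": len(partition.categories),
        "n_category_shapes": len({sh for cat in partition.categories for sh in cat}),
        "giant_component_patches": len(partition.giant_component),
        "n_components": partition.n_components,
        "n_patches": len(patches),
        "modularity": partition.modularity,
    }
    t0 = _stage("categories done", t0)

    metrics["depletion"] = ca.depletion_summary(patches, partition, graph)
    metrics["interleaving"] = {
        k: v for k, v in ca.interleaving_stats(
            partition.categories, graph, k_values=config.k_values,
            max_pairs=config.max_pairs, seed=boot_seed()).items()
        if not k.endswith("distances") and k != "k_step_ratios"
    }
    metrics["transition_ambiguity"] = ca.transition_ambiguity(
        segmentations, partition, logs, n_boot=config.n_boot, seed=boot_seed())
    rnt = ca.road_not_taken(logs, segmentations)
    metrics["road_not_taken"] = {k: v for k, v in rnt.items() if k != "per_shape"}
    t0 = _stage("category statistics done", t0)

    cfg = pm.cfg_score_cohort(logs, segmentations)
    cfg.to_csv(out / "cfg_scores.csv")
    metrics["cfg_scores"] = {
        "fluency_median": float(cfg["fluency"].median()),
        "originality_median": float(cfg["originality"].median()),
        "composite_sd": float(cfg["composite"].std(ddof=0)),
    }

    if truths is not None:
        from .synthetic_data import cohort_boundary_f1, planted_strategy_rho

        metrics["recovery"] = {
            "boundary_f1": cohort_boundary_f1(truths, segmentations),
            "planted_duration_rho": planted_strategy_rho(truths)["duration_rho"],
        }

    _dump_json(metrics, out / "metrics.json")
    _stage("pipeline complete", t0)
    return metrics
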