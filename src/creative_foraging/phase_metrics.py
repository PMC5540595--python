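"""Phase-level statistics of creative-foraging cohorts.

Summaries mirror the original analyses: pooled medians of phase
characteristics with player-bootstrap confidence intervals, the ratio of
shortest to actual path length between consecutive gallery saves (1 means
the player walked a geodesic), Spearman correlations of per-player mean
exploration vs exploitation effort, Mann-Whitney tests with rank-biserial
effect sizes, and the game-side creativity scores (fluency, originality,
and their z-score composite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .game_log import PlayerLog
from .segmentation import EXPLOITATION, EXPLORATION, Segmentation
from .shape_space import MoveGraph, Shape

PHASE_STATS = ["gallery_per_phase", "moves_between_saves", "duration",
               "moves_per_phase", "seconds_per_move"]


# ---------------------------------------------------------------------------
# bootstrap utility


def bootstrap_player_ci(values_by_player: Mapping[str, Sequence[float]],
                        statistic=np.median, n_boot: int = 10_000,
                        seed: Optional[int] = None,
                        level: float = 95.0) -> Tuple[float, Tuple[float, float]]:
    """Pooled statistic with a percentile CI from resampling players.

    Players (not their individual phases) are resampled with replacement,
    their value lists pooled, and the statistic recomputed per replicate.
    """
    players = sorted(values_by_player)
    pooled = [v for pid in players for v in values_by_player[pid]]
    if not pooled:
        raise ValueError("no values to bootstrap")
    point = float(statistic(pooled))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for r in range(n_boot):
        sample: List[float] = []
        for i in rng.integers(0, len(players), len(players)):
            sample.extend(values_by_player[players[i]])
        reps[r] = statistic(sample) if sample else np.nan
    lo, hi = np.nanpercentile(reps, [(100 - level) / 2, 100 - (100 - level) / 2])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Table-1 style summary


def _moves_strictly_between(move_times: Sequence[float], t0: float, t1: float) -> int:
    return sum(1 for t in move_times if t0 < t < t1)


def phase_values(segmentations: Iterable[Segmentation],
                 logs: Iterable[PlayerLog]) -> Dict[str, Dict[str, Dict[str, List[float]]]]:
    """Per-kind, per-statistic value lists keyed by player.

    ``moves_between_saves`` pools one value per consecutive within-phase
    save pair (moves strictly between the two saves); all other statistics
    pool one value per phase.  Phases with no moves contribute no
    seconds-per-move value.
    """
    log_by_id = {log.player_id: log for log in logs}
    out: Dict[str, Dict[str, Dict[str, List[float]]]] = {
        kind: {stat: {} for stat in PHASE_STATS} for kind in (EXPLORATION, EXPLOITATION)
    }
    for seg in segmentations:
        log = log_by_id[seg.player_id]
        move_times = log.move_times()
        gallery_times = [e.t for e in log.events if e.is_gallery]
        for phase in seg.phases:
            bucket = out[phase.kind]
            pid = seg.player_id
            bucket["gallery_per_phase"].setdefault(pid, []).append(phase.n_gallery)
            bucket["duration"].setdefault(pid, []).append(phase.duration)
            bucket["moves_per_phase"].setdefault(pid, []).append(phase.move_count)
            if phase.move_count > 0:
                bucket["seconds_per_move"].setdefault(pid, []).append(
                    phase.duration / phase.move_count)
            for gi in range(phase.gallery_start, phase.gallery_end):
                n_between = _moves_strictly_between(
                    move_times, gallery_times[gi], gallery_times[gi + 1])
                bucket["moves_between_saves"].setdefault(pid, []).append(n_between)
    return out


def phase_summary(segmentations: Iterable[Segmentation], logs: Iterable[PlayerLog],
                  n_boot: int = 10_000, seed: Optional[int] = None) -> pd.DataFrame:
    """Medians and bootstrap 95% CIs of phase characteristics, per kind.

    Returns a frame indexed by statistic with columns
    ``(kind, {"median", "ci_low", "ci_high"})``.  A kind with no phases
    yields empty columns and a warning.
    """
    values = phase_values(list(segmentations), list(logs))
    rows: Dict[str, Dict[Tuple[str, str], float]] = {stat: {} for stat in PHASE_STATS}
    rng = np.random.default_rng(seed)
    for kind in (EXPLORATION, EXPLOITATION):
        for stat in PHASE_STATS:
            by_player = values[kind][stat]
            if not any(by_player.values()):
                warnings.warn(f"no {kind} phases: {stat} column left empty")
                continue
            sub_seed = int(rng.integers(0, 2**31 - 1))
            med, (lo, hi) = bootstrap_player_ci(by_player, np.median, n_boot, sub_seed)
            rows[stat][(kind, "median")] = med
            rows[stat][(kind, "ci_low")] = lo
            rows[stat][(kind, "ci_high")] = hi
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if not frame.empty:
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        frame = frame.reindex(PHASE_STATS)
    return frame


# ---------------------------------------------------------------------------
# path optimality


@dataclass(frozen=True)
class PathRatioRecord:
    """Shortest vs actual path length for one consecutive within-phase save pair."""

    player_id: str
    phase_kind: str
    gallery_pair: Tuple[int, int]
    shortest: int
    actual: int

    @property
    def ratio(self) -> float:
        return self.shortest / self.actual


def path_optimality(log: PlayerLog, segmentation: Segmentation,
                    graph: MoveGraph) -> List[PathRatioRecord]:
    """Geodesic-to-actual ratios for consecutive saves inside each phase.

    Pairs straddling a phase boundary are excluded by construction.  Pairs
    saving the same shape twice (shortest distance 0) are skipped, as are
    distinct saves with no move event between them (corrupt timing).
    """
    gallery = log.gallery_shapes()
    gallery_times = [e.t for e in log.events if e.is_gallery]
    move_times = log.move_times()
    records: List[PathRatioRecord] = []
    for phase in segmentation.phases:
        for gi in range(phase.gallery_start, phase.gallery_end):
            a, b = gallery[gi], gallery[gi + 1]
            if a == b:
                continue
            actual = _moves_strictly_between(move_times, gallery_times[gi],
                                             gallery_times[gi + 1])
            if actual == 0:
                warnings.warn(f"player {log.player_id}: distinct saves {gi},{gi + 1} "
                              "with no moves between; pair skipped")
                continue
            shortest = graph.shortest_path_length(a, b)
            records.append(PathRatioRecord(player_id=log.player_id,
                                           phase_kind=phase.kind,
                                           gallery_pair=(gi, gi + 1),
                                           shortest=shortest, actual=actual))
    return records


def path_ratio_summary(logs: Sequence[PlayerLog], segmentations: Sequence[Segmentation],
                       graph: MoveGraph) -> Dict[str, object]:
    """Cohort view of path optimality, per phase kind.

    Reports the median over players of each player's median ratio (the
    headline statistic), the pooled per-pair median, and a Mann-Whitney
    comparison of the per-player medians between the two kinds.
    """
    seg_by_id = {s.player_id: s for s in segmentations}
    per_player: Dict[str, Dict[str, List[float]]] = {EXPLORATION: {}, EXPLOITATION: {}}
    pooled: Dict[str, List[float]] = {EXPLORATION: [], EXPLOITATION: []}
    for log in logs:
        for rec in path_optimality(log, seg_by_id[log.player_id], graph):
            per_player[rec.phase_kind].setdefault(log.player_id, []).append(rec.ratio)
            pooled[rec.phase_kind].append(rec.ratio)
    out: Dict[str, object] = {}
    player_medians: Dict[str, List[float]] = {}
    for kind in (EXPLORATION, EXPLOITATION):
        medians = [float(np.median(v)) for _, v in sorted(per_player[kind].items())]
        player_medians[kind] = medians
        out[kind] = {
            "player_median": float(np.median(medians)) if medians else None,
            "pooled_median": float(np.median(pooled[kind])) if pooled[kind] else None,
            "n_pairs": len(pooled[kind]),
            "n_players": len(medians),
        }
    if player_medians[EXPLORATION] and player_medians[EXPLOITATION]:
        out["mann_whitney"] = mann_whitney_effect(player_medians[EXPLORATION],
                                                  player_medians[EXPLOITATION])
    return out


# ---------------------------------------------------------------------------
# individual differences


def mann_whitney_effect(sample_a: Sequence[float], sample_b: Sequence[float]) -> Dict[str, float]:
    """Two-sided Mann-Whitney U with the rank-biserial effect size.

    ``effect = |1 - 2U/(n_a * n_b)|`` lies in [0, 1]; 0 for identical
    samples, 1 for fully separated ones.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    effect = abs(1.0 - 2.0 * res.statistic / (a.size * b.size))
    return {"U": float(res.statistic), "p": float(res.pvalue), "effect": float(effect)}


def strategy_means(segmentations: Iterable[Segmentation]) -> pd.DataFrame:
    """Per-player mean phase duration and move count for each phase kind.

    Only players with at least one phase of each kind are kept.
    """
    rows = []
    for seg in segmentations:
        explo = seg.exploration_phases()
        explt = seg.exploitation_phases()
        if not explo or not explt:
            continue
        rows.append({
            "player_id": seg.player_id,
            "exploration_duration": np.mean([p.duration for p in explo]),
            "exploitation_duration": np.mean([p.duration for p in explt]),
            "exploration_moves": np.mean([p.move_count for p in explo]),
            "exploitation_moves": np.mean([p.move_count for p in explt]),
        })
    return pd.DataFrame(rows).set_index("player_id") if rows else pd.DataFrame()


def strategy_correlation(segmentations: Iterable[Segmentation], n_boot: int = 10_000,
                         n_perm: int = 10_000,
                         seed: Optional[int] = None) -> Dict[str, object]:
    """Spearman correlation of exploration vs exploitation effort across players.

    Returns rho for mean phase durations and mean move counts, each with a
    player-bootstrap 95% CI and a permutation p-value.  Raises on fewer than
    three eligible players or on constant inputs (rho undefined).
    """
    frame = strategy_means(segmentations)
    if len(frame) < 3:
        raise ValueError("need at least 3 players with both phase kinds")
    rng = np.random.default_rng(seed)
    out: Dict[str, object] = {"n_players": int(len(frame))}
    for label, (xc, yc) in {
        "duration": ("exploration_duration", "exploitation_duration"),
        "moves": ("exploration_moves", "exploitation_moves"),
    }.items():
        x = frame[xc].to_numpy()
        y = frame[yc].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValueError(f"{label}: constant values, Spearman rho undefined")
        rho = float(stats.spearmanr(x, y).statistic)
        boot = np.empty(n_boot)
        for r in range(n_boot):
            idx = rng.integers(0, len(x), len(x))
            if np.all(x[idx] == x[idx][0]) or np.all(y[idx] == y[idx][0]):
                boot[r] = np.nan
                continue
            boot[r] = stats.spearmanr(x[idx], y[idx]).statistic
        perm_hits = 0
        for _ in range(n_perm):
            perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
            if abs(perm_rho) >= abs(rho):
                perm_hits += 1
        out[f"{label}_rho"] = rho
        out[f"{label}_ci"] = [float(np.nanpercentile(boot, 2.5)),
                              float(np.nanpercentile(boot, 97.5))]
        out[f"{label}_p"] = (perm_hits + 1) / (n_perm + 1)
    return out


# ---------------------------------------------------------------------------
# creativity scores


@dataclass
class CreativityScore:
    """Game-side creativity measures for one player.

    ``fluency`` counts gallery saves made during exploitation phases;
    ``originality`` is the mean rarity ``1 - f_s`` of those shapes, where
    ``f_s`` is the fraction of reference players who ever saved shape ``s``;
    ``composite`` (cohort-level) averages the within-cohort z-scores of the
    two.
    """

    player_id: str
    fluency: int
    originality: Optional[float]
    composite: Optional[float] = None


def save_frequencies(logs: Iterable[PlayerLog]) -> Dict[Shape, float]:
    """Fraction of players who saved each shape at least once."""
    logs = list(logs)
    counts: Dict[Shape, int] = {}
    for log in logs:
        for sh in set(log.gallery_shapes()):
            counts[sh] = counts.get(sh, 0) + 1
    n = len(logs)
    return {sh: c / n for sh, c in counts.items()}


def cfg_scores(log: PlayerLog, segmentation: Segmentation,
               reference_frequencies: Mapping[Shape, float]) -> CreativityScore:
    """Fluency and originality of one player against a reference cohort."""
    gallery = log.gallery_shapes()
    exploit_saves: List[Shape] = []
    for phase in segmentation.exploitation_phases():
        exploit_saves.extend(gallery[i] for i in phase.gallery_indices)
    fluency = len(exploit_saves)
    if fluency == 0:
        warnings.warn(f"player {log.player_id}: no exploitation saves, originality undefined")
        return CreativityScore(player_id=log.player_id, fluency=0, originality=None)
    originality = float(np.mean([1.0 - reference_frequencies.get(sh, 0.0)
                                 for sh in exploit_saves]))
    return CreativityScore(player_id=log.player_id, fluency=fluency, originality=originality)


def cfg_score_cohort(logs: Sequence[PlayerLog], segmentations: Sequence[Segmentation],
                     reference_frequencies: Optional[Mapping[Shape, float]] = None) -> pd.DataFrame:
    """Per-player fluency, originality, and z-score composite.

    Without an explicit reference, shape rarity is scored against this
    cohort itself.  Z-scores use the cohort mean and (population) standard
    deviation; a zero-variance measure z-scores to 0.
    """
    if reference_frequencies is None:
        reference_frequencies = save_frequencies(logs)
    seg_by_id = {s.player_id: s for s in segmentations}
    scores = [cfg_scores(log, seg_by_id[log.player_id], reference_frequencies)
              for log in logs]
    frame = pd.DataFrame({
        "player_id": [s.player_id for s in scores],
        "fluency": [s.fluency for s in scores],
        "originality": [s.originality for s in scores],
    }).set_index("player_id")

    def zscore(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=0)
        if not sd or np.isnan(sd):
            return pd.Series(0.0, index=col.index).where(col.notna())
        return (col - col.mean()) / sd

    frame["z_fluency"] = zscore(frame["fluency"].astype(float))
    frame["z_originality"] = zscore(frame["originality"].astype(float))
    frame["composite"] = frame[["z_fluency", "z_originality"]].mean(axis=1, skipna=False)
    return frame
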