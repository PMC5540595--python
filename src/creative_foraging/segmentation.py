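"""Exploration/exploitation segmentation of gallery-save timing series.

Players alternate between *exploration* (gallery saves spaced further and
further apart) and *exploitation* (a burst of accelerating saves harvesting
one patch of related shapes).  The segmentation works purely on the gaps
``Δ_k`` between consecutive gallery saves and has two passes:

1. maximal strictly-decreasing stretches of at least two gaps become
   candidate exploitation phases;
2. adjacent candidates are merged when the earlier one's largest gap exceeds
   the later one's largest gap, which repairs phases fragmented by a single
   long pause; merging cascades left-to-right to a fixed point.

A candidate over gaps ``Δ_k..Δ_j`` labels gallery events ``k-1..j`` as one
exploitation phase.  Its first event — the *transition shape*, saved before
the phase's longest gap — anchors the phase; the gap into that event still
belongs to the preceding exploration.  Every gallery event left outside all
exploitation phases is exploration.  Equal consecutive gaps terminate a
stretch (monotone means strictly decreasing here).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

from .game_log import DeltaSeries, PlayerLog, gallery_deltas

EXPLORATION = "exploration"
EXPLOITATION = "exploitation"

#: Inclusive (start, end) indices into a delta series.
Run = Tuple[int, int]


@dataclass
class Phase:
    """One exploration or exploitation phase of a single game.

    ``gallery_start``/``gallery_end`` are inclusive indices into the log's
    gallery-event ordering.  ``transition_index`` (exploitation only) is the
    phase's first gallery event.  Time conventions: an exploitation phase
    spans its transition save to its last save; an exploration phase starts
    where the previous phase ended (or at 0) and ends at the next
    exploitation's transition save, so it absorbs the inter-phase gap.
    ``move_count`` counts shape-changing events with ``t_start < t <= t_end``.
    """

    kind: str
    gallery_start: int
    gallery_end: int
    t_start: float
    t_end: float
    move_count: int = 0
    transition_index: Optional[int] = None

    @property
    def gallery_indices(self) -> range:
        return range(self.gallery_start, self.gallery_end + 1)

    @property
    def n_gallery(self) -> int:
        return self.gallery_end - self.gallery_start + 1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Segmentation:
    """Ordered phases partitioning one log's gallery events."""

    player_id: str
    phases: List[Phase] = field(default_factory=list)

    def exploitation_phases(self) -> List[Phase]:
        return [p for p in self.phases if p.kind == EXPLOITATION]

    def exploration_phases(self) -> List[Phase]:
        return [p for p in self.phases if p.kind == EXPLORATION]

    def transition_indices(self) -> List[int]:
        return [p.transition_index for p in self.exploitation_phases()
                if p.transition_index is not None]

    def to_dict(self) -> dict:
        return {
            "player_id": self.player_id,
            "phases": [
                {"kind": p.kind, "gallery_indices": [p.gallery_start, p.gallery_end],
                 "t_start": p.t_start, "t_end": p.t_end, "move_count": p.move_count,
                 "transition_index": p.transition_index}
                for p in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Segmentation":
        phases = [Phase(kind=p["kind"], gallery_start=p["gallery_indices"][0],
                        gallery_end=p["gallery_indices"][1], t_start=p["t_start"],
                        t_end=p["t_end"], move_count=p["move_count"],
                        transition_index=p.get("transition_index"))
                  for p in d["phases"]]
        return cls(player_id=d["player_id"], phases=phases)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _deltas(deltas: Union[DeltaSeries, Sequence[float]]) -> Sequence[float]:
    return deltas.deltas if isinstance(deltas, DeltaSeries) else deltas


def decreasing_runs(deltas: Union[DeltaSeries, Sequence[float]]) -> List[Run]:
    """Maximal strictly decreasing stretches of >= 2 gaps.

    Returned as inclusive ``(start, end)`` delta-index pairs, disjoint and in
    order.  A tie (equal consecutive gaps) breaks a stretch.
    """
    d = _deltas(deltas)
    runs: List[Run] = []
    i = 0
    m = len(d)
    while i < m - 1:
        if d[i] > d[i + 1]:
            j = i + 1
            while j + 1 < m and d[j] > d[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def merge_runs(runs: Sequence[Run], deltas: Union[DeltaSeries, Sequence[float]]) -> List[Run]:
    """Second pass: merge adjacent candidate phases left-to-right.

    Two runs are adjacent when the second starts at the delta immediately
    after the first ends.  They merge when the earlier run's maximal gap
    exceeds the later run's maximal gap; merging cascades until no pair
    qualifies, which de-fragments phases split by one long pause.
    """
    d = _deltas(deltas)

    def peak(run: Run) -> float:
        return max(d[run[0]:run[1] + 1])

    merged: List[Run] = []
    for run in runs:
        cur = run
        while merged and merged[-1][1] + 1 == cur[0] and peak(merged[-1]) > peak(cur):
            prev = merged.pop()
            cur = (prev[0], cur[1])
        merged.append(cur)
    return merged


def segment(log: PlayerLog) -> Segmentation:
    """Label a log's gallery events into alternating phases.

    Each merged run over deltas ``k..j`` yields an exploitation phase over
    gallery events ``k-1..j`` anchored at its transition event ``k-1``; when
    two unmerged runs abut, the contested event stays with the earlier
    phase.  Remaining gallery events form exploration phases.  A log with no
    gallery saves returns an empty segmentation with a warning.
    """
    ds = gallery_deltas(log)
    gt = ds.gallery_times
    m = len(gt)
    seg = Segmentation(player_id=log.player_id)
    if m == 0:
        warnings.warn(f"player {log.player_id}: no gallery events to segment")
        return seg

    runs = merge_runs(decreasing_runs(ds), ds)

    # map runs to disjoint gallery-event ranges
    exploit_ranges: List[Tuple[int, int]] = []
    next_free = 0
    for s, e in runs:
        g_start = max(s, next_free)
        g_end = e + 1
        exploit_ranges.append((g_start, g_end))
        next_free = g_end + 1

    # interleave exploration over the uncovered gallery events
    spans: List[Tuple[str, int, int]] = []
    cursor = 0
    for g_start, g_end in exploit_ranges:
        if cursor < g_start:
            spans.append((EXPLORATION, cursor, g_start - 1))
        spans.append((EXPLOITATION, g_start, g_end))
        cursor = g_end + 1
    if cursor < m:
        spans.append((EXPLORATION, cursor, m - 1))

    move_times = log.move_times()

    def moves_between(t0: float, t1: float) -> int:
        return sum(1 for t in move_times if t0 < t <= t1)

    prev_end = 0.0
    for idx, (kind, g_start, g_end) in enumerate(spans):
        if kind == EXPLOITATION:
            t_start = gt[g_start]
            t_end = gt[g_end]
            transition = g_start
        else:
            t_start = prev_end
            if idx + 1 < len(spans):
                # next span is exploitation: end at its transition save
                t_end = gt[spans[idx + 1][1]]
            else:
                t_end = gt[g_end]
            transition = None
        phase = Phase(kind=kind, gallery_start=g_start, gallery_end=g_end,
                      t_start=t_start, t_end=t_end,
                      move_count=moves_between(t_start, t_end),
                      transition_index=transition)
        seg.phases.append(phase)
        prev_end = t_end
    return seg


def transition_f1(true_transitions: Iterable[int],
                  found_transitions: Iterable[int]) -> float:
    """F1 score between planted and recovered exploitation-phase starts.

    Both arguments are sets of gallery-event indices.  Used to grade the
    segmentation against a simulator's ground truth.
    """
    truth: Set[int] = set(true_transitions)
    found: Set[int] = set(found_transitions)
    if not truth and not found:
        return 1.0
    tp = len(truth & found)
    if tp == 0:
        return 0.0
    precision = tp / len(found)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)
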