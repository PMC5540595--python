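"""Timestamped game trajectories: data model, I/O, and validation.

A game log is the ordered sequence of events of one 15-minute session:
every board state the player passed through plus the moments a shape was
saved to the gallery.  Event times are seconds from game start.  The first
event is the horizontal 10-square line at ``t = 0``.

On disk a cohort is a CSV with header ``player_id,t,shape,is_gallery``
(``shape`` in the ``"r,c;r,c;..."`` encoding, ``is_gallery`` 0/1) or the
equivalent JSONL.  A *move* is an event whose shape differs from the previous
event's shape; a gallery save re-records the current shape with the flag set,
so moves and saves are distinguishable regardless of whether a source logged
them as separate rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, List, Optional, Union

import pandas as pd

from .shape_space import MoveGraph, Shape, is_edge_connected, line_shape

CSV_COLUMNS = ["player_id", "t", "shape", "is_gallery"]


@dataclass(frozen=True)
class Event:
    """One recorded instant: time, current shape, and the gallery flag."""

    t: float
    shape: Shape
    is_gallery: bool


@dataclass
class PlayerLog:
    """Ordered events of one game."""

    player_id: str
    events: List[Event]
    duration: float = 900.0

    def gallery_indices(self) -> List[int]:
        """Event indices of gallery saves, in time order."""
        return [i for i, e in enumerate(self.events) if e.is_gallery]

    def gallery_events(self) -> List[Event]:
        return [e for e in self.events if e.is_gallery]

    def gallery_shapes(self) -> List[Shape]:
        """Saved shapes in save order (the k-th gallery event's shape)."""
        return [e.shape for e in self.events if e.is_gallery]

    def move_times(self) -> List[float]:
        """Times of events that changed the shape."""
        out = []
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.shape != prev.shape:
                out.append(cur.t)
        return out

    @property
    def n(self) -> int:
        return self.events[0].shape.n if self.events else 0


@dataclass
class DeltaSeries:
    """Inter-save gaps: ``deltas[k] = gallery_times[k+1] - gallery_times[k]``."""

    gallery_times: List[float] = field(default_factory=list)
    deltas: List[float] = field(default_factory=list)


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    event_index: int
    rule: str
    message: str
    severity: str = "error"


# ---------------------------------------------------------------------------
# reading / writing


def _logs_from_frame(df: pd.DataFrame, duration: float, source: str) -> List[PlayerLog]:
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        warnings.warn(f"{source}: ignoring unknown columns {extra}")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")

    logs: List[PlayerLog] = []
    bad_rows: List[str] = []
    for player_id, group in df.groupby("player_id", sort=False):
        events: List[Event] = []
        last_t = None
        for row in group.itertuples():
            line_no = row.Index + 2  # header + 1-based
            try:
                t = float(row.t)
                shape = Shape.from_string(str(row.shape))
                flag = bool(int(row.is_gallery))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{source}: malformed row at line {line_no}: {exc}") from exc
            if last_t is not None and t < last_t:
                bad_rows.append(f"line {line_no} (player {player_id}: t={t} < {last_t})")
            last_t = t
            events.append(Event(t=t, shape=shape, is_gallery=flag))
        logs.append(PlayerLog(player_id=str(player_id), events=events, duration=duration))
    if bad_rows:
        raise ValueError(f"{source}: out-of-order timestamps at " + "; ".join(bad_rows))
    return logs


def read_logs(source: Union[str, Path, IO], fmt: Optional[str] = None,
              duration: float = 900.0) -> List[PlayerLog]:
    """Read a cohort of player logs from CSV or JSONL.

    ``fmt`` is inferred from the file suffix when not given.  Rows must be
    grouped or at least time-ordered within each player; out-of-order
    timestamps raise ``ValueError`` naming the offending lines.
    """
    name = str(getattr(source, "name", source))
    if fmt is None:
        fmt = "jsonl" if name.endswith((".jsonl", ".ndjson")) else "csv"
    if fmt == "csv":
        try:
            df = pd.read_csv(source, dtype=str)
        except pd.errors.EmptyDataError:
            return []
    elif fmt == "jsonl":
        rows = []
        close = False
        if isinstance(source, (str, Path)):
            fh = open(source)
            close = True
        else:
            fh = source
        try:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{name}: malformed row at line {i + 1}: {exc}") from exc
        finally:
            if close:
                fh.close()
        if not rows:
            return []
        df = pd.DataFrame(rows)
        df.index = range(-1, len(df) - 1)  # align line numbering with the CSV path
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.empty:
        return []
    return _logs_from_frame(df, duration, name)


def write_logs(logs: Iterable[PlayerLog], path: Union[str, Path], fmt: str = "csv") -> None:
    """Write a cohort in the canonical CSV (default) or JSONL dialect."""
    rows = [
        {"player_id": log.player_id, "t": repr(e.t), "shape": e.shape.to_string(),
         "is_gallery": int(e.is_gallery)}
        for log in logs
        for e in log.events
    ]
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for row in rows:
                row = dict(row, t=float(row["t"]), is_gallery=bool(row["is_gallery"]))
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# validation


def validate_log(log: PlayerLog, graph: MoveGraph) -> List[Violation]:
    """Check a log against the game's rules; returns findings, never raises.

    Errors: wrong cell count, non-canonical/disconnected shapes, a first
    event that is not the horizontal line, decreasing timestamps, times
    beyond the game duration, and transitions that are not single legal
    moves.  Zero gaps between consecutive gallery saves are warnings.
    """
    out: List[Violation] = []
    if not log.events:
        return [Violation(0, "empty log", "log has no events")]

    first = log.events[0]
    if first.shape != line_shape(graph.n):
        out.append(Violation(0, "bad initial shape",
                             f"first shape is {first.shape.to_string()!r}, expected the {graph.n}-line"))
    last_t = None
    last_gallery_t = None
    for i, e in enumerate(log.events):
        if e.shape.n != graph.n:
            out.append(Violation(i, "wrong cell count",
                                 f"shape has {e.shape.n} cells, expected {graph.n}"))
            continue
        if not is_edge_connected(e.shape):
            out.append(Violation(i, "disconnected shape", e.shape.to_string()))
        if e.t < 0:
            out.append(Violation(i, "negative time", f"t={e.t}"))
        if e.t > log.duration:
            out.append(Violation(i, "time beyond duration", f"t={e.t} > {log.duration}"))
        if last_t is not None and e.t < last_t:
            out.append(Violation(i, "out-of-order time", f"t={e.t} < {last_t}"))
        last_t = e.t
        if e.is_gallery:
            if last_gallery_t is not None and e.t == last_gallery_t:
                out.append(Violation(i, "zero gallery delta",
                                     "two gallery saves at the same instant", severity="warning"))
            last_gallery_t = e.t

    for i in range(1, len(log.events)):
        a, b = log.events[i - 1].shape, log.events[i].shape
        if a == b or a.n != graph.n or b.n != graph.n:
            continue
        try:
            legal = b in graph.neighbors(a)
        except KeyError:
            legal = False
        if not legal:
            out.append(Violation(i, "illegal transition",
                                 f"{a.to_string()} -> {b.to_string()} is not one legal move"))
    return out


def gallery_deltas(log: PlayerLog) -> DeltaSeries:
    """Gaps between consecutive gallery saves (moves are ignored).

    Fewer than two saves yield an empty delta list.
    """
    times = [e.t for e in log.events if e.is_gallery]
    deltas = [t1 - t0 for t0, t1 in zip(times, times[1:])]
    return DeltaSeries(gallery_times=times, deltas=deltas)
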