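"""The space of n-square shapes and the legal-move graph that connects them.

A *shape* is a set of ``n`` unit squares on an integer grid, connected
edge-to-edge (diagonal contact does not count).  Shapes are identified up to
translation only: rotations and reflections are distinct.  For ``n = 10``
(the game's decominoes) there are 36,446 such shapes — the census of fixed
polyominoes.

A *legal move* picks up one square whose removal leaves the other ``n - 1``
squares edge-connected and puts it back on any empty grid cell edge-adjacent
to that remainder.  The move relation is symmetric, so the shapes form an
undirected graph whose geodesics define the distance used throughout the
foraging analyses.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from collections import deque
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

Cell = Tuple[int, int]

#: 4-neighbourhood offsets (edge contact only).
NEIGHBOR_OFFSETS: Tuple[Cell, ...] = ((1, 0), (-1, 0), (0, 1), (0, -1))


class Shape(tuple):
    """A canonical shape: a sorted tuple of ``(row, col)`` cells.

    Canonical means ``min(row) == 0`` and ``min(col) == 0``, so two translates
    of the same cell set compare equal.  Instances are immutable, hashable and
    totally ordered by their cell tuple, which gives the deterministic
    serialization order used for tie-breaking and file output.

    Construct via :func:`canonicalize` or :meth:`from_string`; the raw tuple
    constructor performs no normalization.
    """

    __slots__ = ()

    @property
    def n(self) -> int:
        """Number of cells."""
        return len(self)

    def to_string(self) -> str:
        """Serialize as ``"r,c;r,c;..."`` with cells in sorted order."""
        return ";".join(f"{r},{c}" for r, c in self)

    @classmethod
    def from_string(cls, text: str) -> "Shape":
        """Parse the ``"r,c;r,c;..."`` encoding (canonicalizing defensively)."""
        cells = []
        for part in text.strip().split(";"):
            r, c = part.split(",")
            cells.append((int(r), int(c)))
        return canonicalize(cells)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Shape({self.to_string()!r})"


def canonicalize(cells: Iterable[Cell]) -> Shape:
    """Translate a cell set so its bounding box touches row 0 / col 0.

    Duplicate cells are collapsed.  Raises ``ValueError`` on empty input.
    """
    cs = set(cells)
    if not cs:
        raise ValueError("empty shape")
    mr = min(r for r, _ in cs)
    mc = min(c for _, c in cs)
    return Shape(sorted((r - mr, c - mc) for r, c in cs))


def is_edge_connected(cells: Iterable[Cell]) -> bool:
    """True iff the 4-neighbour graph on ``cells`` is connected.

    Empty and singleton sets count as connected.
    """
    cs = set(cells)
    if len(cs) <= 1:
        return True
    start = next(iter(cs))
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr, dc in NEIGHBOR_OFFSETS:
            p = (r + dr, c + dc)
            if p in cs and p not in seen:
                seen.add(p)
                stack.append(p)
    return len(seen) == len(cs)


def line_shape(n: int) -> Shape:
    """The horizontal n-line — the game's initial shape."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Shape((0, c) for c in range(n))


def legal_moves(shape: Shape) -> Set[Shape]:
    """All shapes reachable from ``shape`` by one legal square relocation.

    A square may be picked up only if the remaining cells stay
    edge-connected (pick-up-and-place semantics), and may be dropped on any
    empty cell edge-adjacent to the remainder.  Placements that reproduce a
    translate of the input are discarded, so the result never contains the
    input shape.  For ``n == 1`` the result is empty.
    """
    cells = set(shape)
    out: Set[Shape] = set()
    if len(cells) == 1:
        return out
    for cell in shape:
        rest = cells - {cell}
        if not is_edge_connected(rest):
            continue
        candidates: Set[Cell] = set()
        for r, c in rest:
            for dr, dc in NEIGHBOR_OFFSETS:
                p = (r + dr, c + dc)
                if p not in rest:
                    candidates.add(p)
        candidates.discard(cell)
        for p in candidates:
            new = canonicalize(rest | {p})
            if new != shape:
                out.add(new)
    return out


def enumerate_shapes(n: int) -> Set[Shape]:
    """All canonical edge-connected n-cell shapes, by growth enumeration.

    Starts from the monomino and repeatedly attaches one square to every
    boundary cell, canonicalizing and deduplicating at each generation.
    Every (k+1)-omino has at least one non-cut square, so growing k-ominoes
    by one square reaches the full census.  Runs in ~1 s for ``n = 10``
    (36,446 shapes).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shapes: Set[Shape] = {Shape(((0, 0),))}
    for _ in range(n - 1):
        grown: Set[Shape] = set()
        for sh in shapes:
            occupied = set(sh)
            for r, c in sh:
                for dr, dc in NEIGHBOR_OFFSETS:
                    p = (r + dr, c + dc)
                    if p not in occupied:
                        grown.add(canonicalize(sh + (p,)))
        shapes = grown
    return shapes


def reachability_closure(n: int, start: Optional[Shape] = None) -> Set[Shape]:
    """Closure of :func:`legal_moves` from the n-line (or ``start``).

    Independent cross-check of :func:`enumerate_shapes`: for every ``n`` up to
    10 the move graph is a single component, so the closure equals the census.
    """
    if start is None:
        start = line_shape(n)
    seen = {start}
    queue = deque([start])
    while queue:
        sh = queue.popleft()
        for nb in legal_moves(sh):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen


class MoveGraph:
    """Undirected graph of canonical n-cell shapes under legal moves.

    Two construction modes:

    * :meth:`build` materializes the full node set and adjacency (cheap for
      small ``n``; a few minutes' worth of memory-heavy work at ``n = 10``).
    * :meth:`lazy` enumerates the node set but computes neighbour lists on
      demand, memoizing them.  All queries (distances, paths, balls) work
      identically; this is what the simulator uses on the decomino space.

    Neighbour lists are kept sorted so that path tie-breaking and file output
    are deterministic.
    """

    def __init__(self, n: int, adjacency: Optional[Dict[Shape, Tuple[Shape, ...]]] = None,
                 nodes: Optional[Set[Shape]] = None, lazy: bool = False):
        self.n = n
        self._adj: Dict[Shape, Tuple[Shape, ...]] = adjacency if adjacency is not None else {}
        self._nodes: Optional[Set[Shape]] = nodes
        self._lazy = lazy
        # one canonical instance per shape, so adjacency tuples share objects
        self._intern: Optional[Dict[Shape, Shape]] = None

    def _canon(self, shape: Shape) -> Shape:
        if self._intern is None:
            if self._nodes is None:
                return shape
            self._intern = {sh: sh for sh in self._nodes}
        return self._intern.get(shape, shape)

    # -- construction ----------------------------------------------------

    @classmethod
    def build(cls, n: int) -> "MoveGraph":
        """Materialize the full move graph for ``n``-cell shapes."""
        nodes = enumerate_shapes(n)
        graph = cls(n, nodes=nodes)
        graph._adj = {sh: tuple(sorted(graph._canon(m) for m in legal_moves(sh)))
                      for sh in sorted(nodes)}
        return graph

    @classmethod
    def lazy(cls, n: int, enumerate_nodes: bool = True) -> "MoveGraph":
        """Graph with on-demand, memoized adjacency."""
        nodes = enumerate_shapes(n) if enumerate_nodes else None
        return cls(n, nodes=nodes, lazy=True)

    # -- basic queries ---------------------------------------------------

    @property
    def nodes(self) -> Set[Shape]:
        if self._nodes is None:
            self._nodes = enumerate_shapes(self.n)
        return self._nodes

    def __contains__(self, shape: Shape) -> bool:
        if self._nodes is not None:
            return shape in self._nodes
        return len(shape) == self.n and is_edge_connected(shape)

    def number_of_nodes(self) -> int:
        return len(self.nodes)

    def number_of_edges(self) -> int:
        if self._lazy:
            raise RuntimeError("edge count requires a fully built graph")
        return sum(len(v) for v in self._adj.values()) // 2

    def neighbors(self, shape: Shape) -> Tuple[Shape, ...]:
        """Sorted neighbour tuple of ``shape`` (memoized when lazy)."""
        try:
            return self._adj[shape]
        except KeyError:
            pass
        if not self._lazy or shape not in self:
            raise KeyError(f"shape not in graph: {shape!r}")
        nbrs = tuple(sorted(self._canon(m) for m in legal_moves(shape)))
        self._adj[shape] = nbrs
        return nbrs

    def _require(self, shape: Shape) -> None:
        if shape not in self:
            raise KeyError(f"shape not in graph: {shape!r}")

    # -- geodesics -------------------------------------------------------

    def shortest_path_length(self, a: Shape, b: Shape) -> int:
        """BFS geodesic distance between two shapes (bidirectional search).

        Expands the smaller frontier one full level at a time; when a level
        first touches the opposite search's settled set, the minimum over
        that level's meeting nodes is the exact distance.
        """
        self._require(a)
        self._require(b)
        if a == b:
            return 0
        dist_a: Dict[Shape, int] = {a: 0}
        dist_b: Dict[Shape, int] = {b: 0}
        front_a: List[Shape] = [a]
        front_b: List[Shape] = [b]
        radius_a = radius_b = 0
        while front_a and front_b:
            if len(front_a) > len(front_b):
                front_a, front_b = front_b, front_a
                dist_a, dist_b = dist_b, dist_a
                radius_a, radius_b = radius_b, radius_a
            radius_a += 1
            nxt: List[Shape] = []
            best = None
            for sh in front_a:
                for nb in self.neighbors(sh):
                    if nb not in dist_a:
                        dist_a[nb] = radius_a
                        nxt.append(nb)
                        other = dist_b.get(nb)
                        if other is not None:
                            cand = radius_a + other
                            if best is None or cand < best:
                                best = cand
            if best is not None:
                return best
            front_a = nxt
        raise ValueError(f"no path between {a!r} and {b!r}")

    def shortest_path(self, a: Shape, b: Shape) -> List[Shape]:
        """One geodesic from ``a`` to ``b``.

        Bidirectional BFS with sorted neighbour lists; among the meeting
        nodes of the first touching level the smallest shape (serialization
        order) is chosen, so the returned path is deterministic.
        """
        self._require(a)
        self._require(b)
        if a == b:
            return [a]
        parent_a: Dict[Shape, Optional[Shape]] = {a: None}
        parent_b: Dict[Shape, Optional[Shape]] = {b: None}
        dist_a: Dict[Shape, int] = {a: 0}
        dist_b: Dict[Shape, int] = {b: 0}
        front_a: List[Shape] = [a]
        front_b: List[Shape] = [b]
        swapped = False
        while front_a and front_b:
            if len(front_a) > len(front_b):
                front_a, front_b = front_b, front_a
                dist_a, dist_b = dist_b, dist_a
                parent_a, parent_b = parent_b, parent_a
                swapped = not swapped
            radius = dist_a[front_a[0]] + 1
            nxt: List[Shape] = []
            meets: List[Tuple[int, Shape]] = []
            for sh in front_a:
                for nb in self.neighbors(sh):
                    if nb not in dist_a:
                        dist_a[nb] = radius
                        parent_a[nb] = sh
                        nxt.append(nb)
                        if nb in dist_b:
                            meets.append((radius + dist_b[nb], nb))
            if meets:
                _, meet = min(meets)
                left: List[Shape] = []
                node: Optional[Shape] = meet
                while node is not None:
                    left.append(node)
                    node = parent_a[node]
                left.reverse()
                right: List[Shape] = []
                node = parent_b[meet]
                while node is not None:
                    right.append(node)
                    node = parent_b[node]
                path = left + right
                if swapped:
                    path.reverse()
                return path
            front_a = nxt
        raise ValueError(f"no path between {a!r} and {b!r}")

    def nearest(self, source: Shape, targets: Iterable[Shape]) -> Tuple[Optional[Shape], Optional[int]]:
        """Closest member of ``targets`` to ``source`` and its distance.

        Ties resolve to the smallest shape in serialization order; use
        :meth:`nearest_all` to see every tied candidate.  Returns
        ``(None, None)`` if no target is reachable.
        """
        hits, dist = self.nearest_all(source, targets)
        if not hits:
            return None, None
        return hits[0], dist

    def nearest_all(self, source: Shape, targets: Iterable[Shape]) -> Tuple[List[Shape], Optional[int]]:
        """All equally-closest members of ``targets``, sorted, with distance.

        Multi-target BFS with early exit at the first level containing a
        target.  Returns ``([], None)`` if no target is reachable.
        """
        self._require(source)
        target_set = set(targets)
        if not target_set:
            return [], None
        if source in target_set:
            return [source], 0
        seen = {source}
        frontier = [source]
        dist = 0
        while frontier:
            dist += 1
            nxt = []
            hits = []
            for sh in frontier:
                for nb in self.neighbors(sh):
                    if nb not in seen:
                        seen.add(nb)
                        if nb in target_set:
                            hits.append(nb)
                        nxt.append(nb)
            if hits:
                return sorted(hits), dist
            frontier = nxt
        return [], None

    def ball(self, center: Shape, radius: int) -> Dict[Shape, int]:
        """All shapes within ``radius`` moves of ``center``, with distances."""
        self._require(center)
        dists = {center: 0}
        frontier = [center]
        for d in range(1, radius + 1):
            nxt = []
            for sh in frontier:
                for nb in self.neighbors(sh):
                    if nb not in dists:
                        dists[nb] = d
                        nxt.append(nb)
            frontier = nxt
        return dists

    def is_connected(self) -> bool:
        """Single-component check (requires a built or node-complete graph)."""
        nodes = self.nodes
        start = next(iter(nodes))
        seen = {start}
        stack = [start]
        while stack:
            sh = stack.pop()
            for nb in self.neighbors(sh):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(nodes)

    # -- interop & persistence -------------------------------------------

    def to_networkx(self):
        """Export as ``networkx.Graph`` (materializes adjacency)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for sh in self.nodes:
            for nb in self.neighbors(sh):
                g.add_edge(sh, nb)
        return g

    def save(self, cache_dir: str) -> None:
        """Write ``nodes.txt.gz`` + ``edges.txt.gz`` + ``meta.json``.

        The cache is plain text (one serialized shape per node line, two
        tab-separated shapes per edge line) with an n-keyed checksum so a
        stale cache is rebuilt rather than trusted.
        """
        if self._lazy:
            raise RuntimeError("saving requires a fully built graph")
        os.makedirs(cache_dir, exist_ok=True)
        node_lines = sorted(sh.to_string() for sh in self.nodes)
        with gzip.open(os.path.join(cache_dir, "nodes.txt.gz"), "wt") as fh:
            fh.write("\n".join(node_lines) + "\n")
        edge_lines = []
        for sh in sorted(self.nodes):
            s = sh.to_string()
            for nb in self.neighbors(sh):
                if sh < nb:
                    edge_lines.append(f"{s}\t{nb.to_string()}")
        with gzip.open(os.path.join(cache_dir, "edges.txt.gz"), "wt") as fh:
            fh.write("\n".join(edge_lines) + "\n")
        meta = {
            "n": self.n,
            "nodes": len(node_lines),
            "edges": len(edge_lines),
            "checksum": self._checksum(node_lines),
        }
        with open(os.path.join(cache_dir, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @staticmethod
    def _checksum(node_lines: Sequence[str]) -> str:
        h = hashlib.sha256()
        for line in node_lines:
            h.update(line.encode())
            h.update(b"\n")
        return h.hexdigest()[:16]

    @classmethod
    def load(cls, cache_dir: str) -> "MoveGraph":
        with open(os.path.join(cache_dir, "meta.json")) as fh:
            meta = json.load(fh)
        with gzip.open(os.path.join(cache_dir, "nodes.txt.gz"), "rt") as fh:
            node_lines = [line.strip() for line in fh if line.strip()]
        if meta["checksum"] != cls._checksum(sorted(node_lines)):
            raise ValueError("move-graph cache checksum mismatch; rebuild required")
        nodes = {Shape.from_string(line) for line in node_lines}
        adj: Dict[Shape, List[Shape]] = {sh: [] for sh in nodes}
        with gzip.open(os.path.join(cache_dir, "edges.txt.gz"), "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                a_s, b_s = line.split("\t")
                a, b = Shape.from_string(a_s), Shape.from_string(b_s)
                adj[a].append(b)
                adj[b].append(a)
        frozen = {sh: tuple(sorted(nbrs)) for sh, nbrs in adj.items()}
        return cls(meta["n"], adjacency=frozen, nodes=nodes)

    @classmethod
    def load_or_build(cls, n: int, cache_dir: Optional[str] = None) -> "MoveGraph":
        """Load a cached graph if its checksum matches; otherwise build and cache."""
        if cache_dir is not None:
            try:
                g = cls.load(cache_dir)
                if g.n == n:
                    return g
            except (OSError, ValueError, KeyError):
                pass
        g = cls.build(n)
        if cache_dir is not None:
            g.save(cache_dir)
        return g


def shortest_path_length(graph: MoveGraph, a: Shape, b: Shape) -> int:
    """Geodesic distance in ``graph`` (function-style alias)."""
    return graph.shortest_path_length(a, b)


def shortest_path(graph: MoveGraph, a: Shape, b: Shape) -> List[Shape]:
    """One geodesic path in ``graph`` (function-style alias)."""
    return graph.shortest_path(a, b)
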