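"""Synthetic player cohorts with known ground truth.

The generator emits game logs that are valid against the real move graph
and emulate the structure of the original 100-player, 15-minute dataset:
alternating exploration/exploitation phases, ~3 s per move, gallery saves
that slow down during exploration and accelerate during exploitation,
exploitation saves harvested from planted shape categories along (near-)
geodesic paths, and a per-player tempo that stretches both phase kinds
together, planting the fast-vs-thorough strategy continuum.

Inter-save gaps follow geometric ladders: within an exploration stretch the
gap grows by a factor ``g > 1`` per save; an exploitation burst starts at
its largest gap and shrinks by ``d < 1`` per save.  The first gap of each
burst tops the preceding exploration gap, so the save that opens a burst —
the planted transition shape — anchors a strictly decreasing gap run, which
is exactly the signature the segmentation algorithm detects.  Every planted
phase boundary is recorded as ground truth, making the simulator the oracle
for segmentation recovery, path-optimality mechanics, category recovery,
and the strategy-correlation analysis.

The generator is a test harness that reproduces the statistical signatures
of real games, not a cognitive model of human search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .category_analysis import Patch
from .game_log import Event, PlayerLog
from .segmentation import EXPLOITATION, EXPLORATION, Segmentation, transition_f1
from .shape_space import MoveGraph, Shape, line_shape


@dataclass
class SimParams:
    """Cohort-generator settings; defaults emulate the original study's games.

    100 players, 900 s games on the 10-square space, ~3 s per move, ~7
    exploration/exploitation pairs and ~45 saves per game.  ``gap_base`` is
    the first exploration gap in seconds before tempo scaling; ``gap_growth``
    (> 1) is the geometric factor of the slowing exploration ladder;
    ``gap_decay`` (< 1) is the ratio of a burst's closing gap to its opening
    gap (the acceleration depth of exploitation); ``timing_noise`` is the sigma of the
    multiplicative log-normal jitter on each gap.  ``tempo_sigma`` is the
    sigma of the log-normal per-player tempo; with ``shared_tempo`` one draw
    scales both phase kinds (planting a strong positive strategy
    correlation), otherwise each kind gets an independent draw.  Independent
    draws leave only a small residual coupling (the burst must still open
    above the exploration peak when the explorer is very slow); with
    ``tempo_sigma = 0`` the planted correlation is zero.  Whatever is
    planted, ``planted_strategy_rho`` reports it exactly from ground truth.
    """

    n_players: int = 100
    game_duration: float = 900.0
    n: int = 10
    tempo_sigma: float = 0.4
    shared_tempo: bool = True
    explore_saves: Tuple[int, int] = (1, 2)
    exploit_saves: Tuple[int, int] = (3, 6)
    gap_base: float = 12.0
    gap_growth: float = 1.5
    gap_decay: float = 0.07
    move_seconds: float = 3.0
    timing_noise: float = 0.1
    n_categories: int = 14
    category_size: int = 40
    category_radius: int = 4
    category_overlap: float = 0.1
    exploit_policy: str = "geodesic"  # or "meander"
    meander_epsilon: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gap_growth <= 1:
            raise ValueError("gap_growth must be > 1")
        if not 0 < self.gap_decay < 1:
            raise ValueError("gap_decay must be in (0, 1)")
        for name in ("gap_base", "move_seconds", "game_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.timing_noise < 0 or self.tempo_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.exploit_policy not in ("geodesic", "meander"):
            raise ValueError("exploit_policy must be 'geodesic' or 'meander'")
        if self.exploit_saves[0] < 3:
            # two decreasing gaps (three saves) is the smallest detectable burst
            raise ValueError("exploit_saves must allow at least 3 saves per burst")
        if self.explore_saves[0] < 1:
            raise ValueError("explore_saves must allow at least 1 save per stretch")


@dataclass
class TruePhase:
    """Planted phase: kind, gallery-event range, and timing."""

    kind: str
    gallery_start: int
    gallery_end: int
    t_start: float
    t_end: float
    transition_index: Optional[int] = None
    category_id: Optional[int] = None


@dataclass
class GroundTruth:
    """Everything the generator planted for one player."""

    player_id: str
    tempo_exploration: float
    tempo_exploitation: float
    phases: List[TruePhase] = field(default_factory=list)

    def transition_indices(self) -> List[int]:
        return [p.transition_index for p in self.phases
                if p.kind == EXPLOITATION and p.transition_index is not None]


# ---------------------------------------------------------------------------
# planted categories


def plant_categories(graph: MoveGraph, count: int, radius: int, overlap: float,
                     seed: Optional[int] = None,
                     size: Optional[int] = None) -> List[FrozenSet[Shape]]:
    """Plant ``count`` shape categories as thinned BFS balls around random seeds.

    Each category is the ball of the given radius around a random seed shape,
    thinned (nearest shapes first, serialization order breaking ties) to
    ``size`` members; shapes already claimed by an earlier category are not
    reused, so the cores are disjoint.  When ``overlap > 0``, each category
    after the first additionally absorbs ``round(overlap * size)`` shapes of
    the previous one — the planted ambiguous shapes.  Raises when a ball is
    too small for the requested size.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    categories: List[FrozenSet[Shape]] = []
    used: Set[Shape] = set()
    for ci in range(count):
        ball: Dict[Shape, int] = {}
        for _ in range(50):  # rejection-sample a seed whose ball is big enough
            seed_shape = nodes[int(rng.integers(0, len(nodes)))]
            ball = graph.ball(seed_shape, radius)
            available = [sh for sh in ball if sh not in used]
            target = size if size is not None else len(available)
            if len(available) >= max(target, 1):
                break
        else:
            raise ValueError(f"radius {radius} too small for requested size {size}")
        available.sort(key=lambda sh: (ball[sh], sh))
        target = size if size is not None else len(available)
        if len(available) < target:
            raise ValueError(f"radius {radius} too small for requested size {size}")
        chosen = set(available[:target])
        used.update(chosen)
        if overlap > 0 and categories:
            k = int(round(overlap * len(chosen)))
            prev = sorted(categories[-1])
            idx = rng.choice(len(prev), size=min(k, len(prev)), replace=False)
            chosen.update(prev[i] for i in idx)
        categories.append(frozenset(chosen))
    return categories


def sample_patches_from_planted(categories: Sequence[FrozenSet[Shape]],
                                patches_per_category: int, patch_size: int,
                                seed: Optional[int] = None) -> List[Patch]:
    """Patches drawn from planted categories, chained by >= 2 shared shapes.

    Within each category consecutive patches share two shapes, so each
    category forms one connected blob in the patch network; categories with
    disjoint shape sets produce no cross edges.  Used to test that community
    detection recovers exactly the planted category count.
    """
    rng = np.random.default_rng(seed)
    patches: List[Patch] = []
    for ci, cat in enumerate(categories):
        pool = sorted(cat)
        if len(pool) < patch_size:
            raise ValueError(f"category {ci} smaller than patch size {patch_size}")
        prev: List[Shape] = []
        for pi in range(patches_per_category):
            chosen: Set[Shape] = set()
            if prev:
                idx = rng.choice(len(prev), size=2, replace=False)
                chosen.update(prev[i] for i in idx)
            rest = [sh for sh in pool if sh not in chosen]
            idx = rng.choice(len(rest), size=patch_size - len(chosen), replace=False)
            chosen.update(rest[i] for i in idx)
            shapes = sorted(chosen)
            patches.append(Patch(player_id=f"cat{ci}", phase_index=pi,
                                 shapes=frozenset(shapes),
                                 departure_shape=shapes[-1]))
            prev = shapes
    return patches


# ---------------------------------------------------------------------------
# one player


def _random_step(graph: MoveGraph, current: Shape, previous: Optional[Shape],
                 rng: np.random.Generator) -> Shape:
    nbrs = graph.neighbors(current)
    if previous is not None and len(nbrs) > 1:
        nbrs = tuple(nb for nb in nbrs if nb != previous)
    return nbrs[int(rng.integers(0, len(nbrs)))]


def _walk_random(graph: MoveGraph, current: Shape, steps: int,
                 rng: np.random.Generator) -> List[Shape]:
    """Meandering walk of exactly ``steps`` moves (no immediate backtracking)."""
    path: List[Shape] = []
    prev: Optional[Shape] = None
    for _ in range(steps):
        nxt = _random_step(graph, current, prev, rng)
        path.append(nxt)
        prev, current = current, nxt
    return path


def _walk_to_target(graph: MoveGraph, current: Shape, target: Shape,
                    epsilon: float, rng: np.random.Generator,
                    extra_steps: int = 0) -> List[Shape]:
    """Walk ending exactly at ``target``.

    ``extra_steps`` meandering moves first, then an epsilon-greedy descent:
    each move follows the geodesic with probability ``1 - epsilon`` and a
    random neighbour otherwise (epsilon 0 gives the pure geodesic).  A step
    cap prevents unbounded meandering on unlucky draws.
    """
    path = _walk_random(graph, current, extra_steps, rng)
    if path:
        current = path[-1]
    if current == target:
        return path
    if epsilon <= 0:
        path.extend(graph.shortest_path(current, target)[1:])
        return path
    budget = 6 * max(1, graph.shortest_path_length(current, target)) + 20
    prev: Optional[Shape] = None
    while current != target:
        if budget > 0 and rng.random() < epsilon:
            nxt = _random_step(graph, current, prev, rng)
        else:
            nxt = graph.shortest_path(current, target)[1]
        path.append(nxt)
        prev, current = current, nxt
        budget -= 1
    return path


def _phase_pair_plan(rng: np.random.Generator, params: SimParams,
                     prev_burst_floor: float, tempo_exploration: float,
                     tempo_exploitation: float,
                     ) -> Tuple[List[float], float, List[float], float]:
    """Tempo-scaled gap ladder for one exploration stretch + one burst.

    Planned directly in scaled seconds so the inequalities the segmentation
    keys on hold for every tempo combination: exploration gaps rise
    geometrically from the base pace (restarting strictly above the previous
    burst's floor), the gap into the transition save continues the rise, and
    the burst opens above that peak before shrinking to ``gap_decay`` of its
    opening gap.  The exploitation save count scales with the exploitation
    tempo (slow-to-drop players harvest more saves, planting the move-count
    side of the strategy correlation); the burst's opening gap is anchored
    on the exploitation tempo with a one-factor margin over the exploration
    peak, so with independent tempos the two phase kinds stay (nearly)
    uncoupled.  Returns (exploration gaps, gap into the transition save,
    exploitation gaps after the transition, this burst's floor gap).
    """
    g, d = params.gap_growth, params.gap_decay
    lo_e, hi_e = params.explore_saves
    lo_x, hi_x = params.exploit_saves
    m_e = int(rng.integers(lo_e, hi_e + 1))
    m_x = int(np.clip(round(rng.integers(lo_x, hi_x + 1) * tempo_exploitation),
                      lo_x, lo_x + 6))
    first = max(params.gap_base * tempo_exploration, prev_burst_floor * g)
    explore_gaps = [first * g ** j for j in range(m_e)]
    into_transition = first * g ** m_e
    # the burst opens above the deepest possible exploration peak (exponent
    # hi_e + 2, not m_e + 2), so its magnitude does not leak the length of
    # the exploration stretch into the exploitation durations
    burst_top = max(into_transition * g,
                    params.gap_base * g ** (hi_e + 2) * tempo_exploitation)
    # the burst interpolates geometrically from its opening gap down to the
    # floor d * burst_top regardless of the save count
    exploit_gaps = [burst_top * d ** (j / (m_x - 2)) for j in range(m_x - 1)]
    return explore_gaps, into_transition, exploit_gaps, exploit_gaps[-1]


def simulate_player(graph: MoveGraph, params: SimParams,
                    categories: Sequence[FrozenSet[Shape]],
                    seed: Optional[int] = None,
                    player_id: str = "p000",
                    tempo_exploration: Optional[float] = None,
                    tempo_exploitation: Optional[float] = None,
                    ) -> Tuple[PlayerLog, GroundTruth]:
    """Simulate one game and return the log plus its planted ground truth.

    Exploration: random walk with saves at geometrically lengthening gaps.
    Exploitation: lock onto the category nearest the current shape, then
    visit its nearest-unvisited members — along geodesics or an
    epsilon-greedy meander — saving each at geometrically shrinking gaps.
    Move events are spread evenly inside each inter-save gap, so slower
    players (higher tempo) both take longer and make more moves.  A phase
    pair is only started if its whole gap ladder fits into the remaining
    game time, so planted boundaries are never truncated mid-burst.
    """
    rng = np.random.default_rng(seed)
    if tempo_exploration is None:
        tempo_exploration = float(rng.lognormal(0.0, params.tempo_sigma))
    if tempo_exploitation is None:
        tempo_exploitation = tempo_exploration if params.shared_tempo else float(
            rng.lognormal(0.0, params.tempo_sigma))

    all_category_shapes: Set[Shape] = set()
    for cat in categories:
        all_category_shapes.update(cat)
    if not all_category_shapes:
        raise ValueError("no category shapes to exploit")

    start = line_shape(params.n)
    events: List[Event] = [Event(t=0.0, shape=start, is_gallery=False)]
    truth = GroundTruth(player_id=player_id, tempo_exploration=tempo_exploration,
                        tempo_exploitation=tempo_exploitation)
    current = start
    t = 0.0
    gi = 0  # next gallery-event index
    prev_burst_floor = 0.0
    epsilon = params.meander_epsilon if params.exploit_policy == "meander" else 0.0

    def noise() -> float:
        if params.timing_noise == 0:
            return 1.0
        return float(rng.lognormal(0.0, params.timing_noise))

    def emit(gap: float, path: List[Shape], save: bool) -> None:
        """Append ``path`` moves evenly inside ``gap`` then a save event."""
        nonlocal current, t
        t0 = t
        for i, sh in enumerate(path):
            events.append(Event(t=t0 + gap * (i + 1) / (len(path) + 1),
                                shape=sh, is_gallery=False))
        if path:
            current = path[-1]
        t = t0 + gap
        if save:
            events.append(Event(t=t, shape=current, is_gallery=True))

    while len(truth.phases) < 1000:  # safety bound; duration breaks the loop
        explore_gaps, into_transition, exploit_gaps, burst_floor = _phase_pair_plan(
            rng, params, prev_burst_floor, tempo_exploration, tempo_exploitation)
        if not truth.phases:
            # a very slow player's first pair may overshoot the game; retry
            # it at minimal save counts before declaring the game too short
            total = sum(explore_gaps) + into_transition + sum(exploit_gaps)
            if t + total > params.game_duration:
                explore_gaps, into_transition, exploit_gaps, burst_floor = \
                    _phase_pair_plan(rng, params, prev_burst_floor,
                                     tempo_exploration, 0.0)
        scaled_explore = [g * noise() for g in explore_gaps]
        scaled_into = into_transition * noise()
        scaled_exploit = [g * noise() for g in exploit_gaps]
        if t + sum(scaled_explore) + scaled_into + sum(scaled_exploit) > params.game_duration:
            break

        # exploration stretch: meandering walk, saves where the walk stands
        explore_start_t = t
        explore_gi = gi
        for gap in scaled_explore:
            steps = max(1, int(round(gap / params.move_seconds)))
            emit(gap, _walk_random(graph, current, steps, rng), save=True)
            gi += 1

        # approach a nearest fresh category shape (ties broken by the
        # player's rng, so different players enter through different doors);
        # saving it opens the burst
        hits, _ = graph.nearest_all(current, all_category_shapes - {current})
        assert hits
        target = hits[int(rng.integers(0, len(hits)))]
        cat_id = int(rng.choice([i for i, cat in enumerate(categories)
                                 if target in cat]))
        steps = max(0, int(round(scaled_into / params.move_seconds))
                    - graph.shortest_path_length(current, target))
        emit(scaled_into, _walk_to_target(graph, current, target, 0.0, rng,
                                          extra_steps=steps), save=True)
        transition_gi = gi
        gi += 1
        truth.phases.append(TruePhase(kind=EXPLORATION, gallery_start=explore_gi,
                                      gallery_end=transition_gi - 1,
                                      t_start=explore_start_t, t_end=t))
        burst_start_t = t

        # exploitation burst: harvest nearest-unvisited members of the category
        visited: Set[Shape] = {target}
        for gap in scaled_exploit:
            nxt_hits, _ = graph.nearest_all(current, set(categories[cat_id]) - visited)
            if not nxt_hits:
                break  # category exhausted (only possible with tiny categories)
            nxt_target = nxt_hits[int(rng.integers(0, len(nxt_hits)))]
            emit(gap, _walk_to_target(graph, current, nxt_target, epsilon, rng),
                 save=True)
            visited.add(nxt_target)
            gi += 1
        truth.phases.append(TruePhase(kind=EXPLOITATION, gallery_start=transition_gi,
                                      gallery_end=gi - 1, t_start=burst_start_t,
                                      t_end=t, transition_index=transition_gi,
                                      category_id=cat_id))
        prev_burst_floor = burst_floor

    if not truth.phases:
        raise ValueError("game duration too short for a single phase pair")
    log = PlayerLog(player_id=player_id, events=events,
                    duration=params.game_duration)
    return log, truth


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(graph: MoveGraph, params: SimParams,
                    seed: Optional[int] = None,
                    categories: Optional[Sequence[FrozenSet[Shape]]] = None,
                    ) -> Tuple[List[PlayerLog], List[GroundTruth], List[FrozenSet[Shape]]]:
    """Simulate a cohort; returns (logs, ground truths, planted categories).

    Each player's RNG stream derives from ``(cohort seed, player index)``,
    so cohorts are reproducible and players mutually independent.  The
    cohort seed defaults to ``params.seed``.
    """
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    cat_ss, *player_ss = ss.spawn(params.n_players + 1)
    if categories is None:
        categories = plant_categories(
            graph, params.n_categories, params.category_radius,
            params.category_overlap, seed=cat_ss,
            size=params.category_size)
    logs: List[PlayerLog] = []
    truths: List[GroundTruth] = []
    for i in range(params.n_players):
        log, truth = simulate_player(graph, params, categories, seed=player_ss[i],
                                     player_id=f"p{i:03d}")
        logs.append(log)
        truths.append(truth)
    return logs, truths, list(categories)


def planted_strategy_rho(truths: Sequence[GroundTruth]) -> Dict[str, float]:
    """Spearman correlation planted in a cohort's true phase durations.

    The oracle for strategy-correlation recovery: per-player mean phase
    durations straight from the ground truth, bypassing segmentation.
    """
    xs, ys = [], []
    for truth in truths:
        explo = [p.t_end - p.t_start for p in truth.phases if p.kind == EXPLORATION]
        explt = [p.t_end - p.t_start for p in truth.phases if p.kind == EXPLOITATION]
        if explo and explt:
            xs.append(np.mean(explo))
            ys.append(np.mean(explt))
    rho = float(stats.spearmanr(xs, ys).statistic)
    return {"duration_rho": rho, "n_players": len(xs)}


def cohort_boundary_f1(truths: Sequence[GroundTruth],
                       segmentations: Sequence[Segmentation]) -> float:
    """Mean per-player F1 between planted and recovered transition indices."""
    seg_by_id = {s.player_id: s for s in segmentations}
    scores = [transition_f1(truth.transition_indices(),
                            seg_by_id[truth.player_id].transition_indices())
              for truth in truths]
    return float(np.mean(scores))
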