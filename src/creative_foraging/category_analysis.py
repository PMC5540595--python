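"""Shape categories from the patch-overlap network, and what players do with them.

Each exploitation phase yields a *patch*: the set of shapes its player saved
while harvesting one vein of related shapes.  Patches from the whole cohort
form an undirected network — two patches are linked when they share at least
two shapes — and the communities of its giant component, found with the
Girvan–Newman edge-betweenness algorithm cut at maximum modularity, define
the cohort's *shape categories* (digits, airplanes, letters, ... in the
original data).  On top of the partition this module computes:

* per-visit category coverage and the distance from a patch's departure
  shape to the nearest unharvested category member (patch-depletion tests);
* within- versus between-category geodesic distributions and the k-step
  same-category reachability ratio (interleaving of categories in shape
  space);
* the ambiguity excess of transition shapes (membership in >= 2 categories);
* the "road not taken" share: how often a visit to a transition shape
  actually starts an exploitation phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .game_log import PlayerLog
from .segmentation import Segmentation
from .shape_space import MoveGraph, Shape

PatchKey = Tuple[str, int]


@dataclass(frozen=True)
class Patch:
    """Shapes saved in one exploitation phase of one player."""

    player_id: str
    phase_index: int  # ordinal among the player's exploitation phases
    shapes: FrozenSet[Shape]
    departure_shape: Shape  # last gallery shape of the phase

    @property
    def key(self) -> PatchKey:
        return (self.player_id, self.phase_index)


@dataclass
class CategoryPartition:
    """Communities of the giant component and the shape sets they aggregate.

    ``communities[i]`` is a set of patch keys; ``categories[i]`` is the union
    of those patches' shapes.  A shape may belong to several categories when
    patches containing it fall into different communities — that is exactly
    the ambiguity the transition-shape analysis measures.  Patches outside
    the giant component belong to no category.
    """

    communities: List[FrozenSet[PatchKey]]
    categories: List[FrozenSet[Shape]]
    giant_component: FrozenSet[PatchKey]
    n_components: int
    modularity: float

    def shape_memberships(self) -> Dict[Shape, FrozenSet[int]]:
        """Map each categorized shape to the set of category ids containing it."""
        out: Dict[Shape, Set[int]] = {}
        for i, cat in enumerate(self.categories):
            for sh in cat:
                out.setdefault(sh, set()).add(i)
        return {sh: frozenset(ids) for sh, ids in out.items()}

    def community_of_patch(self) -> Dict[PatchKey, int]:
        return {key: i for i, comm in enumerate(self.communities) for key in comm}


def extract_patches(segmentations: Iterable[Segmentation],
                    logs: Iterable[PlayerLog]) -> List[Patch]:
    """One patch per exploitation phase; duplicate saves collapse."""
    log_by_id = {log.player_id: log for log in logs}
    patches: List[Patch] = []
    for seg in segmentations:
        log = log_by_id[seg.player_id]
        gallery = log.gallery_shapes()
        for k, phase in enumerate(seg.exploitation_phases()):
            shapes = frozenset(gallery[i] for i in phase.gallery_indices)
            patches.append(Patch(player_id=seg.player_id, phase_index=k,
                                 shapes=shapes,
                                 departure_shape=gallery[phase.gallery_end]))
    return patches


def build_patch_network(patches: Sequence[Patch]) -> nx.Graph:
    """Graph over patches; an edge means the two patches share >= 2 shapes.

    Isolated patches are kept as degree-0 nodes.  Node keys are
    ``(player_id, phase_index)`` with the patch stored as a node attribute.
    """
    if not patches:
        raise ValueError("no patches")
    g = nx.Graph()
    for p in patches:
        g.add_node(p.key, patch=p)
    by_shape: Dict[Shape, List[Patch]] = {}
    for p in patches:
        for sh in p.shapes:
            by_shape.setdefault(sh, []).append(p)
    pair_counts: Dict[Tuple[PatchKey, PatchKey], int] = {}
    for holders in by_shape.values():
        for i in range(len(holders)):
            for j in range(i + 1, len(holders)):
                a, b = holders[i], holders[j]
                key = (a.key, b.key) if a.key < b.key else (b.key, a.key)
                pair_counts[key] = pair_counts.get(key, 0) + 1
    for (ka, kb), count in pair_counts.items():
        if count >= 2:
            g.add_edge(ka, kb)
    return g


def _deterministic_heaviest_edge(graph: nx.Graph):
    """Highest edge betweenness; ties broken by sorted edge key."""
    centrality = nx.edge_betweenness_centrality(graph)
    return max(centrality, key=lambda e: (centrality[e], tuple(sorted(e))))


def detect_categories(network: nx.Graph,
                      patience: Optional[int] = None) -> CategoryPartition:
    """Girvan–Newman communities of the giant component, cut at max modularity.

    The dendrogram level with the highest Newman–Girvan modularity wins;
    the trivial one-community partition (modularity 0) is the baseline, so a
    network with no community structure stays undivided.  Tie-breaking is
    deterministic: betweenness ties resolve by edge serialization order and
    only strictly better modularity replaces the incumbent.

    ``patience`` (off by default) stops descending the dendrogram after that
    many consecutive levels without a modularity improvement — a pragmatic
    cap for large networks, where modularity is unimodal-ish along the
    dendrogram and the full descent costs quadratically in edges.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty patch network")
    components = sorted(nx.connected_components(network),
                        key=lambda c: (-len(c), sorted(c)))
    giant = components[0]
    sub = network.subgraph(giant).copy()

    best_partition: List[Set[PatchKey]] = [set(giant)]
    best_q = 0.0
    since_best = 0
    if len(giant) >= 3 and sub.number_of_edges() > 0:
        for partition in nx.community.girvan_newman(
                sub, most_valuable_edge=_deterministic_heaviest_edge):
            q = nx.community.modularity(sub, partition)
            if q > best_q:
                best_q = q
                best_partition = [set(c) for c in partition]
                since_best = 0
            else:
                since_best += 1
                if patience is not None and since_best >= patience:
                    break

    communities = sorted((frozenset(c) for c in best_partition),
                         key=lambda c: (-len(c), sorted(c)))
    categories = []
    for comm in communities:
        shapes: Set[Shape] = set()
        for key in comm:
            shapes.update(network.nodes[key]["patch"].shapes)
        categories.append(frozenset(shapes))
    return CategoryPartition(communities=list(communities), categories=categories,
                             giant_component=frozenset(giant),
                             n_components=len(components), modularity=best_q)


# ---------------------------------------------------------------------------
# depletion


def coverage_per_visit(patch: Patch, category: FrozenSet[Shape]) -> float:
    """Fraction of a category's shapes harvested in one visit."""
    if not category:
        raise ValueError("empty category")
    return len(patch.shapes & category) / len(category)


def departure_distance(patch: Patch, category: FrozenSet[Shape],
                       graph: MoveGraph) -> Optional[int]:
    """Moves from the departure shape to the nearest unharvested category shape.

    ``None`` (with a warning) when the visit exhausted the category.
    """
    remaining = category - patch.shapes
    if patch.departure_shape in remaining:
        return 0
    if not remaining:
        warnings.warn(f"patch {patch.key}: category exhausted, no departure distance")
        return None
    _, dist = graph.nearest(patch.departure_shape, remaining)
    return dist


def depletion_summary(patches: Sequence[Patch], partition: CategoryPartition,
                      graph: MoveGraph) -> Dict[str, object]:
    """Cohort means of per-visit coverage and departure distance."""
    comm_of = partition.community_of_patch()
    coverages: List[float] = []
    distances: List[int] = []
    for p in patches:
        ci = comm_of.get(p.key)
        if ci is None:
            continue
        category = partition.categories[ci]
        coverages.append(coverage_per_visit(p, category))
        d = departure_distance(p, category, graph)
        if d is not None:
            distances.append(d)
    return {
        "mean_coverage": float(np.mean(coverages)) if coverages else None,
        "mean_departure_distance": float(np.mean(distances)) if distances else None,
        "n_patches": len(coverages),
    }


# ---------------------------------------------------------------------------
# interleaving


def interleaving_stats(categories: Sequence[FrozenSet[Shape]], graph: MoveGraph,
                       k_values: Sequence[int] = (1, 2, 3, 4, 5),
                       max_pairs: Optional[int] = None,
                       seed: Optional[int] = None) -> Dict[str, object]:
    """Are categories segregated islands or interleaved in shape space?

    Computes geodesic distances over all within-category and between-category
    shape pairs (optionally subsampled to ``max_pairs`` per distribution),
    and, for each categorized shape and each ``K`` in ``k_values``, the ratio
    of same-category to other-category shapes reachable within ``K`` moves.
    Interleaved categories give similar distance distributions and a small
    ratio; segregated ones give a between-median far above the within-median.
    """
    membership: Dict[Shape, Set[int]] = {}
    for i, cat in enumerate(categories):
        for sh in cat:
            membership.setdefault(sh, set()).add(i)
    shapes = sorted(membership)
    rng = np.random.default_rng(seed)

    within_pairs: List[Tuple[Shape, Shape]] = []
    between_pairs: List[Tuple[Shape, Shape]] = []
    for i in range(len(shapes)):
        for j in range(i + 1, len(shapes)):
            a, b = shapes[i], shapes[j]
            if membership[a] & membership[b]:
                within_pairs.append((a, b))
            else:
                between_pairs.append((a, b))

    def sample(pairs: List[Tuple[Shape, Shape]]) -> List[Tuple[Shape, Shape]]:
        if max_pairs is None or len(pairs) <= max_pairs:
            return pairs
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        return [pairs[i] for i in sorted(idx)]

    within = [graph.shortest_path_length(a, b) for a, b in sample(within_pairs)]
    between = [graph.shortest_path_length(a, b) for a, b in sample(between_pairs)]

    ratios: List[float] = []
    k_max = max(k_values)
    for sh in shapes:
        mine = membership[sh]
        ball = graph.ball(sh, k_max)  # one BFS serves every K
        same_by_d = dict.fromkeys(range(k_max + 1), 0)
        other_by_d = dict.fromkeys(range(k_max + 1), 0)
        for nb, dist in ball.items():
            if nb == sh or nb not in membership:
                continue
            if membership[nb] & mine:
                same_by_d[dist] += 1
            else:
                other_by_d[dist] += 1
        for k in k_values:
            same = sum(same_by_d[d] for d in range(k + 1))
            other = sum(other_by_d[d] for d in range(k + 1))
            if other > 0:
                ratios.append(same / other)

    return {
        "within_distances": within,
        "between_distances": between,
        "within_median": float(np.median(within)) if within else None,
        "between_median": float(np.median(between)) if between else None,
        "k_step_ratios": ratios,
        "k_step_ratio_median": float(np.median(ratios)) if ratios else None,
    }


# ---------------------------------------------------------------------------
# transition shapes


def transition_ambiguity(segmentations: Iterable[Segmentation],
                         partition: CategoryPartition,
                         logs: Iterable[PlayerLog],
                         n_boot: int = 10_000,
                         seed: Optional[int] = None) -> Dict[str, object]:
    """Are transition shapes more ambiguous than other exploitation saves?

    A shape is *ambiguous* when it belongs to >= 2 categories.  Compares the
    ambiguous share among transition saves (first save of each exploitation
    phase) to the share among the remaining exploitation saves, counting
    save occurrences and only shapes that belong to at least one category.
    Confidence intervals bootstrap over players.
    """
    if not partition.categories:
        raise ValueError("no categories")
    membership = partition.shape_memberships()
    log_by_id = {log.player_id: log for log in logs}

    per_player: Dict[str, Tuple[List[bool], List[bool]]] = {}
    for seg in segmentations:
        gallery = log_by_id[seg.player_id].gallery_shapes()
        trans: List[bool] = []
        non_trans: List[bool] = []
        for phase in seg.exploitation_phases():
            for gi in phase.gallery_indices:
                sh = gallery[gi]
                ids = membership.get(sh)
                if ids is None:
                    continue
                (trans if gi == phase.transition_index else non_trans).append(len(ids) >= 2)
        if trans or non_trans:
            per_player[seg.player_id] = (trans, non_trans)

    players = sorted(per_player)

    def shares(chosen: Sequence[str]) -> Tuple[Optional[float], Optional[float]]:
        t_flags: List[bool] = []
        n_flags: List[bool] = []
        for pid in chosen:
            t, n = per_player[pid]
            t_flags.extend(t)
            n_flags.extend(n)
        ts = float(np.mean(t_flags)) if t_flags else None
        ns = float(np.mean(n_flags)) if n_flags else None
        return ts, ns

    t_share, n_share = shares(players)
    rng = np.random.default_rng(seed)
    t_boot: List[float] = []
    n_boot_vals: List[float] = []
    for _ in range(n_boot):
        resampled = [players[i] for i in rng.integers(0, len(players), len(players))]
        ts, ns = shares(resampled)
        if ts is not None:
            t_boot.append(ts)
        if ns is not None:
            n_boot_vals.append(ns)

    def ci(vals: List[float]) -> Optional[List[float]]:
        if not vals:
            return None
        return [float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))]

    return {
        "transition_share": t_share,
        "nontransition_share": n_share,
        "transition_median_boot": float(np.median(t_boot)) if t_boot else None,
        "nontransition_median_boot": float(np.median(n_boot_vals)) if n_boot_vals else None,
        "transition_ci": ci(t_boot),
        "nontransition_ci": ci(n_boot_vals),
    }


def road_not_taken(logs: Iterable[PlayerLog], segmentations: Iterable[Segmentation],
                   transition_shapes: Optional[Iterable[Shape]] = None) -> Dict[str, object]:
    """How often does reaching a transition shape actually start an exploitation?

    For each transition shape, among the players whose trajectory visits it
    at all, the fraction for whom it anchors one of their own exploitation
    phases.  The complement is the "road not taken".  Returns the mean over
    transition shapes plus the per-shape detail.
    """
    logs = list(logs)
    segmentations = list(segmentations)
    log_by_id = {log.player_id: log for log in logs}

    starts_by_player: Dict[str, Set[Shape]] = {}
    for seg in segmentations:
        gallery = log_by_id[seg.player_id].gallery_shapes()
        starts_by_player[seg.player_id] = {gallery[i] for i in seg.transition_indices()}

    if transition_shapes is None:
        all_transitions: Set[Shape] = set()
        for s in starts_by_player.values():
            all_transitions |= s
    else:
        all_transitions = set(transition_shapes)

    visited_by_player = {log.player_id: {e.shape for e in log.events} for log in logs}

    fractions: Dict[str, float] = {}
    values: List[float] = []
    for sh in sorted(all_transitions):
        visitors = [pid for pid, visited in visited_by_player.items() if sh in visited]
        if not visitors:
            continue
        exploiters = sum(1 for pid in visitors if sh in starts_by_player.get(pid, ()))
        frac = exploiters / len(visitors)
        fractions[sh.to_string()] = frac
        values.append(frac)
    return {
        "mean_fraction": float(np.mean(values)) if values else None,
        "n_transition_shapes": len(values),
        "per_shape": fractions,
    }
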