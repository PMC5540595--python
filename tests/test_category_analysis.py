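"""Patch network construction, community detection, and category statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from creative_foraging.category_analysis import (CategoryPartition, Patch,
                                                 build_patch_network,
                                                 coverage_per_visit,
                                                 departure_distance,
                                                 detect_categories,
                                                 depletion_summary,
                                                 extract_patches,
                                                 interleaving_stats,
                                                 road_not_taken,
                                                 transition_ambiguity)
from creative_foraging.game_log import Event, PlayerLog
from creative_foraging.segmentation import (EXPLOITATION, EXPLORATION, Phase,
                                            Segmentation)
from creative_foraging.shape_space import Shape
from creative_foraging.synthetic_data import (plant_categories,
                                              sample_patches_from_planted)


def patch(pid, idx, shapes):
    shapes = sorted(shapes)
    return Patch(player_id=pid, phase_index=idx, shapes=frozenset(shapes),
                 departure_shape=shapes[-1])


def fake_shape(i):
    """Distinct single-row shapes standing in for real saves."""
    return Shape(tuple((0, c) for c in range(i + 1)))


# ---------------------------------------------------------------------------
# patches


def test_extract_patches_counts_and_dedupes(small_cohort):
    patches = extract_patches(small_cohort["segmentations"], small_cohort["logs"])
    expected = sum(len(s.exploitation_phases()) for s in small_cohort["segmentations"])
    assert len(patches) == expected
    seg = small_cohort["segmentations"][0]
    log = small_cohort["logs"][0]
    gallery = log.gallery_shapes()
    first = next(p for p in patches if p.player_id == log.player_id and p.phase_index == 0)
    phase = seg.exploitation_phases()[0]
    assert first.shapes == {gallery[i] for i in phase.gallery_indices}
    assert first.departure_shape == gallery[phase.gallery_end]


def test_patch_count_matches_planted_phases(small_cohort):
    patches = extract_patches(small_cohort["segmentations"], small_cohort["logs"])
    planted = sum(1 for tr in small_cohort["truths"] for p in tr.phases
                  if p.kind == EXPLOITATION)
    assert len(patches) == planted


# ---------------------------------------------------------------------------
# the >= 2 shared-shapes rule


def test_edge_rule_examples():
    s = [fake_shape(i) for i in range(7)]
    a = patch("a", 0, [s[1], s[2], s[3]])
    b = patch("b", 0, [s[2], s[3], s[4]])
    c = patch("c", 0, [s[5], s[6]])
    g = build_patch_network([a, b, c])
    assert set(g.nodes) == {a.key, b.key, c.key}
    assert set(map(frozenset, g.edges)) == {frozenset({a.key, b.key})}


def test_single_shared_shape_is_no_edge():
    s = [fake_shape(i) for i in range(5)]
    a = patch("a", 0, [s[0], s[1]])
    b = patch("b", 0, [s[1], s[2]])
    g = build_patch_network([a, b])
    assert g.number_of_edges() == 0
    assert g.number_of_nodes() == 2  # isolated patches are kept


def test_edge_rule_matches_bruteforce_on_random_patches():
    rng = np.random.default_rng(4)
    shapes = [fake_shape(i) for i in range(12)]
    patches = [patch(f"p{i}", 0,
                     [shapes[j] for j in rng.choice(12, size=4, replace=False)])
               for i in range(15)]
    g = build_patch_network(patches)
    for a, b in itertools.combinations(patches, 2):
        expected = len(a.shapes & b.shapes) >= 2
        assert g.has_edge(a.key, b.key) == expected


# ---------------------------------------------------------------------------
# community detection


def brute_force_best_modularity(graph):
    """Maximum Newman-Girvan modularity over all partitions (<= 8 nodes)."""
    nodes = sorted(graph.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield part + [[head]]

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(graph, [set(c) for c in part])
        best = max(best, q)
    return best


def network_from_nx(g):
    """Wrap an abstract graph's nodes in dummy patches for detect_categories."""
    out = nx.Graph()
    for node in g.nodes:
        p = patch(f"n{node}", 0, [fake_shape(node)])
        out.add_node(("n%d" % node, 0), patch=p)
    for u, v in g.edges:
        out.add_edge((f"n{u}", 0), (f"n{v}", 0))
    return out


def test_two_cliques_yield_two_communities():
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(range(4), 2))
    g.add_edges_from(itertools.combinations(range(4, 8), 2))
    g.add_edge(0, 4)
    partition = detect_categories(network_from_nx(g))
    assert len(partition.communities) == 2
    sizes = sorted(len(c) for c in partition.communities)
    assert sizes == [4, 4]
    assert partition.modularity == pytest.approx(
        brute_force_best_modularity(g.subgraph(range(8))))


def test_single_clique_is_one_community():
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(range(5), 2))
    partition = detect_categories(network_from_nx(g))
    assert len(partition.communities) == 1
    assert partition.modularity == 0.0


@pytest.mark.parametrize("builder", [
    lambda: nx.barbell_graph(3, 1),
    lambda: nx.path_graph(7),
    lambda: nx.lollipop_graph(4, 3),
    lambda: nx.full_rary_tree(2, 7),
])
def test_max_modularity_matches_exhaustive_search(builder):
    """On small graphs with block structure the dendrogram cut at maximum
    modularity coincides with exhaustive modularity maximization.  (This is
    not a theorem for arbitrary graphs: the edge-betweenness dendrogram of
    the 8-cycle, for instance, never contains the optimal 3-arc partition.)
    """
    g = builder()
    partition = detect_categories(network_from_nx(g))
    assert partition.modularity == pytest.approx(brute_force_best_modularity(g))


@pytest.mark.parametrize("k", [2, 3, 4, 5])
def test_planted_categories_are_recovered_exactly(graph6, k):
    # patch size 5 from 8-shape categories: any two same-category patches
    # share >= 2 shapes by pigeonhole, so each planted category is one clique
    planted = plant_categories(graph6, count=k, radius=3, overlap=0.0,
                               seed=50 + k, size=8)
    patches = sample_patches_from_planted(planted, patches_per_category=6,
                                          patch_size=5, seed=k)
    network = build_patch_network(patches)
    # disjoint planted sets: exactly one network component per category
    partition = detect_categories(network)
    assert partition.n_components == k
    comps = list(nx.connected_components(network))
    assert len(comps) == k
    for comp in comps:
        sub_partition = detect_categories(network.subgraph(comp))
        assert len(sub_partition.communities) == 1


def test_planted_categories_with_bridges_split_into_k_communities(graph6):
    k = 3
    planted = plant_categories(graph6, count=k, radius=3, overlap=0.0,
                               seed=77, size=8)
    patches = sample_patches_from_planted(planted, patches_per_category=6,
                                          patch_size=5, seed=9)
    # weak bridge patches (two shapes from an actual patch of each pair of
    # categories) pull everything into one giant component
    first = {p.player_id: p for p in patches if p.phase_index == 0}
    for i, (a, b) in enumerate([("cat0", "cat1"), ("cat1", "cat2")]):
        shapes = sorted(first[a].shapes)[:2] + sorted(first[b].shapes)[:2]
        patches.append(patch("bridge", i, shapes))
    partition = detect_categories(build_patch_network(patches))
    assert partition.n_components == 1
    core_map = {}
    for i, comm in enumerate(partition.communities):
        for key in comm:
            if key[0].startswith("cat"):
                core_map.setdefault(key[0], set()).add(i)
    # every planted category's patches stay together, and none are merged
    assert all(len(v) == 1 for v in core_map.values())
    assert len({next(iter(v)) for v in core_map.values()}) == k


# ---------------------------------------------------------------------------
# depletion


def test_coverage_per_visit():
    s = [fake_shape(i) for i in range(12)]
    p = patch("a", 0, s[:3])
    assert coverage_per_visit(p, frozenset(s)) == pytest.approx(0.25)
    assert coverage_per_visit(p, frozenset(s[4:])) == 0.0
    with pytest.raises(ValueError):
        coverage_per_visit(p, frozenset())


def test_departure_distance_cases(graph5):
    nodes = sorted(graph5.nodes)
    a = nodes[0]
    nbr = graph5.neighbors(a)[0]
    p = Patch(player_id="a", phase_index=0, shapes=frozenset({a}),
              departure_shape=a)
    assert departure_distance(p, frozenset({a, nbr}), graph5) == 1
    # departure shape itself still unharvested -> 0
    p2 = Patch(player_id="a", phase_index=0, shapes=frozenset({nbr}),
               departure_shape=a)
    assert departure_distance(p2, frozenset({a, nbr}), graph5) == 0
    with pytest.warns(UserWarning, match="exhausted"):
        assert departure_distance(p, frozenset({a}), graph5) is None


# ---------------------------------------------------------------------------
# interleaving


def test_segregated_categories_have_larger_between_distances(graph6):
    nodes = sorted(graph6.nodes)
    a = nodes[0]
    b = max(nodes, key=lambda sh: graph6.shortest_path_length(a, sh))
    ball_a = frozenset(graph6.ball(a, 1))
    ball_b = frozenset(graph6.ball(b, 1))
    out = interleaving_stats([ball_a, ball_b - ball_a], graph6, k_values=(1, 2))
    assert out["between_median"] > out["within_median"]


def test_single_category_has_no_between_distances(graph5):
    cat = frozenset(graph5.ball(sorted(graph5.nodes)[0], 1))
    out = interleaving_stats([cat], graph5, k_values=(1,))
    assert out["between_distances"] == []
    assert out["between_median"] is None


# ---------------------------------------------------------------------------
# ambiguity and the road not taken


def manual_partition(categories):
    return CategoryPartition(communities=[frozenset({(f"x{i}", 0)})
                                          for i in range(len(categories))],
                             categories=[frozenset(c) for c in categories],
                             giant_component=frozenset(), n_components=1,
                             modularity=0.0)


def test_ambiguity_membership_rule():
    s = [fake_shape(i) for i in range(6)]
    partition = manual_partition([s[:3], s[2:5]])
    memberships = partition.shape_memberships()
    assert len(memberships[s[2]]) == 2   # ambiguous
    assert len(memberships[s[0]]) == 1


def test_transition_ambiguity_shares():
    s = [fake_shape(i) for i in range(6)]
    partition = manual_partition([s[:3], s[2:5]])
    sh = s
    log = PlayerLog(player_id="p0", events=[
        Event(0.0, sh[0], False),
        Event(1.0, sh[2], True),   # transition save: ambiguous
        Event(2.0, sh[0], True),   # harvest: unambiguous
        Event(3.0, sh[1], True),   # harvest: unambiguous
    ])
    seg = Segmentation(player_id="p0", phases=[
        Phase(kind=EXPLOITATION, gallery_start=0, gallery_end=2,
              t_start=1.0, t_end=3.0, transition_index=0)])
    out = transition_ambiguity([seg], partition, [log], n_boot=100, seed=0)
    assert out["transition_share"] == 1.0
    assert out["nontransition_share"] == 0.0


def test_transition_ambiguity_requires_categories():
    partition = CategoryPartition(communities=[], categories=[],
                                  giant_component=frozenset(), n_components=0,
                                  modularity=0.0)
    with pytest.raises(ValueError):
        transition_ambiguity([], partition, [], n_boot=100)


def test_road_not_taken_extremes():
    s = [fake_shape(i) for i in range(4)]
    log1 = PlayerLog(player_id="p1", events=[
        Event(0.0, s[0], False), Event(1.0, s[1], True),
        Event(2.0, s[2], True), Event(3.0, s[3], True)])
    seg1 = Segmentation(player_id="p1", phases=[
        Phase(kind=EXPLOITATION, gallery_start=0, gallery_end=2,
              t_start=1.0, t_end=3.0, transition_index=0)])
    # player 2 passes through s[1] without exploiting there
    log2 = PlayerLog(player_id="p2", events=[
        Event(0.0, s[0], False), Event(1.0, s[1], False),
        Event(2.0, s[2], True)])
    seg2 = Segmentation(player_id="p2", phases=[
        Phase(kind=EXPLORATION, gallery_start=0, gallery_end=0,
              t_start=0.0, t_end=2.0)])
    out = road_not_taken([log1, log2], [seg1, seg2])
    # s[1] is the only transition shape; both players visited it, one exploited
    assert out["n_transition_shapes"] == 1
    assert out["mean_fraction"] == pytest.approx(0.5)


def test_depletion_summary_on_cohort(small_cohort):
    patches = extract_patches(small_cohort["segmentations"], small_cohort["logs"])
    partition = detect_categories(build_patch_network(patches))
    out = depletion_summary(patches, partition, small_cohort["graph"])
    assert out["n_patches"] > 0
    assert 0 < out["mean_coverage"] <= 1
    assert out["mean_departure_distance"] is None or out["mean_departure_distance"] >= 0
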