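"""Phase summaries, path-ratio mechanics, correlations, creativity scores."""

import numpy as np
import pytest

from creative_foraging.game_log import Event, PlayerLog
from creative_foraging.phase_metrics import (bootstrap_player_ci,
                                             cfg_score_cohort, cfg_scores,
                                             mann_whitney_effect, path_optimality,
                                             path_ratio_summary, phase_summary,
                                             save_frequencies,
                                             strategy_correlation)
from creative_foraging.segmentation import (EXPLOITATION, EXPLORATION, Phase,
                                            Segmentation)
from creative_foraging.shape_space import line_shape


def log_along_path(path, save_at, player_id="p0"):
    """Log that walks ``path`` at 3 s per move, saving at the given path indices."""
    events = [Event(0.0, path[0], False)]
    t = 0.0
    if 0 in save_at:
        events.append(Event(t + 1.0, path[0], True))
        t += 1.0
    for i, sh in enumerate(path[1:], start=1):
        t += 3.0
        events.append(Event(t, sh, False))
        if i in save_at:
            events.append(Event(t + 1.0, sh, True))
            t += 1.0
    return PlayerLog(player_id=player_id, events=events)


# ---------------------------------------------------------------------------
# Table-1 style summary


def hand_segmentation(player_id="p0"):
    phases = [
        Phase(kind=EXPLORATION, gallery_start=0, gallery_end=1,
              t_start=0.0, t_end=60.0, move_count=20),
        Phase(kind=EXPLOITATION, gallery_start=2, gallery_end=4,
              t_start=60.0, t_end=100.0, move_count=10, transition_index=2),
    ]
    return Segmentation(player_id=player_id, phases=phases)


def hand_log(player_id="p0"):
    sh = line_shape(3)
    times = [10.0, 30.0, 60.0, 80.0, 100.0]
    events = [Event(0.0, sh, False)]
    events += [Event(t, sh, True) for t in times]
    return PlayerLog(player_id=player_id, events=events)


def test_phase_summary_hand_medians():
    frame = phase_summary([hand_segmentation()], [hand_log()], n_boot=200, seed=0)
    assert frame.loc["gallery_per_phase", (EXPLORATION, "median")] == 2
    assert frame.loc["gallery_per_phase", (EXPLOITATION, "median")] == 3
    assert frame.loc["duration", (EXPLORATION, "median")] == 60.0
    assert frame.loc["duration", (EXPLOITATION, "median")] == 40.0
    assert frame.loc["seconds_per_move", (EXPLOITATION, "median")] == 4.0


def test_identical_players_give_zero_width_cis():
    segs = [hand_segmentation(f"p{i}") for i in range(5)]
    logs = [hand_log(f"p{i}") for i in range(5)]
    frame = phase_summary(segs, logs, n_boot=200, seed=0)
    lo = frame.loc["duration", (EXPLOITATION, "ci_low")]
    hi = frame.loc["duration", (EXPLOITATION, "ci_high")]
    assert lo == hi == 40.0


def test_missing_kind_warns():
    seg = Segmentation(player_id="p0", phases=[hand_segmentation().phases[1]])
    with pytest.warns(UserWarning, match="no exploration"):
        frame = phase_summary([seg], [hand_log()], n_boot=200, seed=0)
    assert (EXPLOITATION, "median") in frame.columns


def test_bootstrap_ci_narrows_with_cohort_size():
    rng = np.random.default_rng(3)

    def cohort(n):
        return {f"p{i}": list(rng.normal(10, 3, size=5)) for i in range(n)}

    _, (lo_s, hi_s) = bootstrap_player_ci(cohort(20), np.median, n_boot=400, seed=1)
    _, (lo_l, hi_l) = bootstrap_player_ci(cohort(100), np.median, n_boot=400, seed=1)
    assert (hi_l - lo_l) < (hi_s - lo_s)


# ---------------------------------------------------------------------------
# path optimality


def test_geodesic_walk_scores_ratio_one(graph5):
    nodes = sorted(graph5.nodes)
    a = nodes[0]
    b = next(sh for sh in nodes if graph5.shortest_path_length(a, sh) == 3)
    path = graph5.shortest_path(a, b)
    log = log_along_path(path, save_at={0, 3})
    seg = Segmentation(player_id="p0", phases=[
        Phase(kind=EXPLOITATION, gallery_start=0, gallery_end=1,
              t_start=0.0, t_end=log.events[-1].t, transition_index=0)])
    records = path_optimality(log, seg, graph5)
    assert len(records) == 1
    rec = records[0]
    assert rec.actual == 3 and rec.shortest == 3
    assert rec.ratio == 1.0


def test_ratio_arithmetic():
    from creative_foraging.phase_metrics import PathRatioRecord

    rec = PathRatioRecord(player_id="p", phase_kind=EXPLOITATION,
                          gallery_pair=(0, 1), shortest=2, actual=6)
    assert rec.ratio == pytest.approx(1 / 3)


def test_repeated_save_pairs_are_skipped(graph5):
    sh = line_shape(5)
    log = PlayerLog(player_id="p0", events=[
        Event(0.0, sh, False), Event(5.0, sh, True), Event(9.0, sh, True)])
    seg = Segmentation(player_id="p0", phases=[
        Phase(kind=EXPLORATION, gallery_start=0, gallery_end=1,
              t_start=0.0, t_end=9.0)])
    assert path_optimality(log, seg, graph5) == []


def test_cohort_ratio_contrast(small_cohort):
    out = path_ratio_summary(small_cohort["logs"], small_cohort["segmentations"],
                             small_cohort["graph"])
    # geodesic harvesting scores exactly 1; random-walk exploration scores below
    assert out[EXPLOITATION]["player_median"] == 1.0
    assert out[EXPLORATION]["player_median"] < 1.0
    assert out["mann_whitney"]["effect"] > 0.5


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_identical_samples_have_zero_effect():
    out = mann_whitney_effect([1, 2, 3, 4], [1, 2, 3, 4])
    assert out["effect"] == pytest.approx(0.0)


def test_mann_whitney_separated_samples_have_full_effect():
    out = mann_whitney_effect([1, 2], [3, 4])
    assert out["U"] == 0.0
    assert out["effect"] == pytest.approx(1.0)


def test_mann_whitney_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_effect([], [1.0])


# ---------------------------------------------------------------------------
# strategy correlation


def seg_with_durations(player_id, explo, explt):
    phases = [Phase(kind=EXPLORATION, gallery_start=0, gallery_end=0,
                    t_start=0.0, t_end=explo, move_count=int(explo)),
              Phase(kind=EXPLOITATION, gallery_start=1, gallery_end=3,
                    t_start=explo, t_end=explo + explt,
                    move_count=int(explt), transition_index=1)]
    return Segmentation(player_id=player_id, phases=phases)


def test_monotone_pairs_give_rho_one():
    segs = [seg_with_durations(f"p{i}", 10.0 + i, 20.0 + 2 * i) for i in range(8)]
    out = strategy_correlation(segs, n_boot=200, n_perm=200, seed=0)
    assert out["duration_rho"] == pytest.approx(1.0)
    assert out["duration_p"] < 0.05


def test_constant_values_are_degenerate():
    segs = [seg_with_durations(f"p{i}", 10.0, 20.0) for i in range(5)]
    with pytest.raises(ValueError, match="undefined"):
        strategy_correlation(segs, n_boot=200, n_perm=200, seed=0)


def test_too_few_players_raises():
    segs = [seg_with_durations("p0", 10.0, 20.0)]
    with pytest.raises(ValueError, match="at least 3"):
        strategy_correlation(segs, n_boot=200, n_perm=200, seed=0)


# ---------------------------------------------------------------------------
# creativity scores


def test_fluency_counts_exploitation_saves(small_cohort):
    log = small_cohort["logs"][0]
    seg = small_cohort["segmentations"][0]
    expected = sum(p.n_gallery for p in seg.exploitation_phases())
    score = cfg_scores(log, seg, {})
    assert score.fluency == expected
    # unseen shapes are maximally original under 1 - f
    assert score.originality == pytest.approx(1.0)


def test_universally_saved_shapes_score_zero_originality():
    log = hand_log()
    seg = hand_segmentation()
    freqs = {sh: 1.0 for sh in log.gallery_shapes()}
    score = cfg_scores(log, seg, freqs)
    assert score.originality == pytest.approx(0.0)


def test_no_exploitation_saves_warns():
    log = hand_log()
    seg = Segmentation(player_id="p0", phases=[hand_segmentation().phases[0]])
    with pytest.warns(UserWarning, match="originality undefined"):
        score = cfg_scores(log, seg, {})
    assert score.fluency == 0 and score.originality is None


def test_equal_players_get_equal_composites(small_cohort):
    frame = cfg_score_cohort(small_cohort["logs"], small_cohort["segmentations"])
    dup = frame[frame.duplicated(["fluency", "originality"], keep=False)]
    for _, grp in dup.groupby(["fluency", "originality"]):
        assert grp["composite"].nunique() == 1
    # composite is the mean of the two z-scores
    row = frame.iloc[0]
    assert row["composite"] == pytest.approx(
        (row["z_fluency"] + row["z_originality"]) / 2)


def test_save_frequencies_are_player_fractions(small_cohort):
    freqs = save_frequencies(small_cohort["logs"])
    assert freqs and all(0 < f <= 1 for f in freqs.values())
    some_shape = next(iter(freqs))
    count = sum(1 for log in small_cohort["logs"]
                if some_shape in set(log.gallery_shapes()))
    assert freqs[some_shape] == pytest.approx(count / len(small_cohort["logs"]))
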