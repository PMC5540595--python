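import pytest

from creative_foraging.segmentation import segment
from creative_foraging.shape_space import MoveGraph
from creative_foraging.synthetic_data import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def graph4():
    return MoveGraph.build(4)


@pytest.fixture(scope="session")
def graph5():
    return MoveGraph.build(5)


@pytest.fixture(scope="session")
def graph6():
    return MoveGraph.build(6)


def small_params(**overrides) -> SimParams:
    """Cohort settings scaled down to the 5-square toy space for fast tests."""
    base = dict(n_players=12, n=5, n_categories=3, category_size=8,
                category_radius=3, category_overlap=0.1, timing_noise=0.0)
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_cohort(graph5):
    """A noise-free 12-player cohort on the 5-square space, with truth and segmentations."""
    params = small_params()
    logs, truths, categories = simulate_cohort(graph5, params, seed=202)
    segs = [segment(log) for log in logs]
    return {"params": params, "logs": logs, "truths": truths,
            "categories": categories, "segmentations": segs, "graph": graph5}
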