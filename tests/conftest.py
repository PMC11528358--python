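import numpy as np
import pytest

from socage.edges import PosteriorNetworkDraw
from socage.synthetic import GeneratorConfig, GroupYearObservations


@pytest.fixture(scope="session")
def tiny_obs() -> GroupYearObservations:
    """Hand-built 4-individual group-year with known bout counts."""
    return GroupYearObservations(
        label="tiny",
        ids=("a", "b", "c", "d"),
        ages=(6, 10, 18, 28),
        focal_counts=(10, 10, 20, 10),
        dyads={("a", "b"): 10, ("b", "c"): 3, ("c", "d"): 1},
    )


@pytest.fixture(scope="session")
def paper_scale_study() -> list[GroupYearObservations]:
    """Default-configuration study at the emulated observation scale."""
    from socage.synthetic import generate_study

    return generate_study(GeneratorConfig(n_group_years=30, rng_seed=2024))


def make_draw(weights, ages=None, label="net", threshold=0.01, draw_index=0):
    """PosteriorNetworkDraw from an explicit symmetric weight matrix."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    ids = tuple(chr(ord("A") + k) for k in range(n))
    return PosteriorNetworkDraw(
        label=label,
        draw_index=draw_index,
        ids=ids,
        ages=tuple(ages) if ages is not None else (10,) * n,
        weights=w,
        threshold=threshold,
    )


@pytest.fixture
def two_node():
    def _build(weight, ages=(10, 10)):
        return make_draw([[0.0, weight], [weight, 0.0]], ages=ages)

    return _build
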