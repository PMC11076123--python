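import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from propagule import CommunityComposition, IndividualSample
from propagule.synthetic import PANEL_NAMES


def random_composition(rng: np.random.Generator, k: int, floor: float = 1e-3) -> CommunityComposition:
    """A random k-group composition with every proportion >= floor.

    The floor (0.1%, just below the rarest observed group at 0.14%) keeps
    compositions in the realistic range and makes large-N limits finite.
    """
    p = rng.dirichlet(np.ones(k))
    p = np.maximum(p, floor)
    return CommunityComposition(tuple(f"g{i}" for i in range(k)), p / p.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def comp_maker():
    return random_composition


def make_sample(iid, caste, counts, colony="I", sex="unknown"):
    full = {name: 0 for name in PANEL_NAMES}
    full.update(counts)
    return IndividualSample(
        individual_id=iid, colony_id=colony, caste_group=caste, sex=sex, counts=full
    )


@pytest.fixture
def small_samples():
    """Four hand-built individuals across two castes and colonies."""
    return [
        make_sample("w1", "worker", {"Pyrsonympha spp.": 50, "Tr. agilis": 50}),
        make_sample("w2", "worker", {"Pyrsonympha spp.": 90, "Tr. agilis": 10}, colony="II"),
        make_sample("n1", "nymph", {"Pyrsonympha spp.": 30, "Te. mirabilis": 10}),
        make_sample("n2", "nymph", {"Pyrsonympha spp.": 5, "Te. mirabilis": 5}, colony="II"),
    ]
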