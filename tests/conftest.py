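import numpy as np
import pytest

from nmasplit.fixtures import figure_networks, parkinson_network
from nmasplit.network_core import ArmMeasurement, Network, Study


@pytest.fixture(scope="session")
def parkinson():
    return parkinson_network()


@pytest.fixture(scope="session")
def figures():
    return figure_networks()


@pytest.fixture(scope="session")
def figure_skeletons(figures):
    return {name: fix.skeleton_network() for name, fix in figures.items()}


def make_arm_study(study_id, arms, means=None, sd=1.0, n=10):
    """Small helper: arm-based study with given treatments and means."""
    arms = tuple(arms)
    if means is None:
        means = [float(i) for i in range(len(arms))]
    return Study(
        id=str(study_id),
        measurements=tuple(
            ArmMeasurement(treatment=t, mean=float(m), std_dev=sd, sample_size=n)
            for t, m in zip(arms, means)
        ),
    )


def make_network(*treatment_sets):
    """Network of placeholder arm studies from raw treatment tuples."""
    return Network(
        studies=tuple(
            make_arm_study(i + 1, arms) for i, arms in enumerate(treatment_sets)
        )
    )


def random_small_network(rng: np.random.Generator) -> Network:
    """Random connected-or-not small network: <=5 treatments, <=6 studies."""
    m = rng.integers(3, 6)
    treatments = list("abcde"[:m])
    n_studies = rng.integers(2, 7)
    sets = []
    for _ in range(n_studies):
        size = rng.integers(2, min(4, m) + 1)
        sets.append(tuple(sorted(rng.choice(treatments, size=size, replace=False))))
    return make_network(*sets)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
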