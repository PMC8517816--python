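import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from companionbn import (
    ContextProfile,
    LevelDistribution,
    load_default_model,
)


@pytest.fixture(scope="session")
def model():
    """The shipped default knowledge base (anxiety fully elicited)."""
    return load_default_model()


@pytest.fixture(scope="session")
def anxiety(model):
    return model.dimension("anxiety")


@pytest.fixture(scope="session")
def man_over_18():
    return ContextProfile("man", "over_18")


def point_mass(level):
    return LevelDistribution.point_mass(level)


def random_level_distribution(rng: np.random.Generator, zeros_ok: bool = False):
    """A random 4-level distribution; optionally with structural zeros."""
    w = rng.dirichlet(np.ones(4))
    if zeros_ok and rng.random() < 0.3:
        keep = rng.choice(4, size=rng.integers(1, 4), replace=False)
        mask = np.zeros(4)
        mask[keep] = w[keep]
        w = mask / mask.sum()
    return LevelDistribution(w)
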