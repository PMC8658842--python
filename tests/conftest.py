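import pytest
from hypothesis import settings

from g3ps import (
    Feature,
    FixtureSpec,
    Pharmacophore,
    perturbed_copy,
    random_pharmacophore,
)

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def simple_pharmacophore() -> Pharmacophore:
    """Four well-separated features of distinct types."""
    return Pharmacophore(
        name="simple",
        features=[
            Feature("H", (0.0, 0.0, 0.0), 1.0),
            Feature("AR", (4.0, 0.0, 0.0), 1.5, direction=(0, 0, 1)),
            Feature("HBA", (0.0, 4.0, 0.0), 1.2, direction=(1, 0, 0)),
            Feature("HBD", (2.0, 2.0, 3.0), 1.0),
        ],
    )


@pytest.fixture
def random_pair():
    """A 6-feature random pharmacophore and an exact rigid copy."""
    A = random_pharmacophore(FixtureSpec(n_features=6, seed=42))
    B, truth = perturbed_copy(A, rigid=True, seed=43)
    return A, B, truth


def make_random(n: int, seed: int, **kw) -> Pharmacophore:
    return random_pharmacophore(FixtureSpec(n_features=n, seed=seed, **kw))
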