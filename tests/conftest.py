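import itertools

import pytest
from hypothesis import HealthCheck, settings

import vennkit as vk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_force_regions(sets: dict[str, set[str]]) -> dict[str, int]:
    """Independent region oracle: direct set algebra per subset.

    For every non-empty subset S of set names, the exclusive region is
    (∩ S) \\ (∪ complement), computed with plain Python set operations.
    Returns canonical signature -> element count, empty regions omitted.
    """
    names = list(sets)
    out: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            region = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    region -= sets[other]
            if region:
                out["&".join(combo)] = len(region)
    return out


@pytest.fixture
def toy_pair() -> vk.SetCollection:
    """A = {x, y}, B = {y}."""
    return vk.SetCollection.from_sets({"A": ["x", "y"], "B": ["y"]})


@pytest.fixture
def toy_triple() -> vk.SetCollection:
    """Nested A ⊇ B ⊇ C on three elements."""
    return vk.SetCollection.from_sets(
        {"A": ["1", "2", "3"], "B": ["2", "3"], "C": ["3"]}
    )


@pytest.fixture
def random_collection() -> vk.SetCollection:
    return vk.generate_collection(4, 150, seed=42)
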