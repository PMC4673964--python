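import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pharmequity import EconomicAnchors, GroupedDistribution

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def anchors() -> EconomicAnchors:
    # Arbitrary currency units: everything downstream is relative.
    return EconomicAnchors(cpl=10.0, nmw=8.0)


def random_distribution(rng: np.random.Generator) -> GroupedDistribution:
    """A random valid grouped distribution with 2-10 groups."""
    t = int(rng.integers(2, 11))
    pop = rng.uniform(0.1, 5.0, size=t)
    mass = rng.uniform(0.0, 10.0, size=t)
    if mass.sum() <= 0:  # pragma: no cover - essentially impossible
        mass[0] = 1.0
    return GroupedDistribution(tuple(f"g{i}" for i in range(t)), pop, mass)
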