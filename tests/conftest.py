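import random

import pytest
from hypothesis import HealthCheck, settings

from fccfold import FCC, Conformation, random_saw

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_conformation(n: int, seed: int, h_fraction: float = 0.5) -> Conformation:
    """Seeded random self-avoiding FCC walk with an i.i.d. random HP sequence."""
    rng = random.Random(seed)
    seq = "".join("H" if rng.random() < h_fraction else "P" for _ in range(n))
    return Conformation(seq, tuple(random_saw(n, rng, FCC)))


@pytest.fixture
def rhombus():
    """Four monomers on a closed FCC rhombus: one non-consecutive contact."""
    return Conformation("HHHH", ((0, 0, 0), (1, 1, 0), (2, 0, 0), (1, -1, 0)))


@pytest.fixture
def straight_hpph():
    return Conformation("HPPH", ((0, 0, 0), (1, 1, 0), (2, 2, 0), (3, 3, 0)))
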