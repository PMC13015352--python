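import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from filafrag import Cell, Filament

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_filament(pole_pairs, compounds=None, conn_ages=None):
    """Build a filament from explicit per-cell state for oracle tests."""
    n = len(pole_pairs)
    compounds = compounds if compounds is not None else [0.0] * n
    cells = [
        Cell(pole_age_left=a, pole_age_right=b, compound=c)
        for (a, b), c in zip(pole_pairs, compounds)
    ]
    from filafrag import Connection

    conns = (
        None
        if conn_ages is None
        else [Connection(age=a) for a in conn_ages]
    )
    return Filament(cells, conns)


@pytest.fixture
def build_filament():
    return make_filament
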