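import numpy as np
import pytest

from repskew.datasets import (
    load_black_bear_males,
    load_great_tit_matrix_excerpt,
    load_great_tit_summary,
)
from repskew.simulate import SimScenario


@pytest.fixture(scope="session")
def bear():
    """Male black bear vital rates + per-age raw statistics (annual example)."""
    return load_black_bear_males()


@pytest.fixture(scope="session")
def tit_summary():
    """Great tit per-age-at-death LRS summary (lifetime example)."""
    return load_great_tit_summary()


@pytest.fixture(scope="session")
def tit_matrix():
    """Five-row excerpt of the great tit per-individual matrix."""
    return load_great_tit_matrix_excerpt()


@pytest.fixture
def rng():
    return np.random.default_rng(20231120)


@pytest.fixture
def reference_scenario():
    """Five age classes, 50% survival, stabilized fecundity, Poisson variance."""
    def make(**kwargs):
        defaults = dict(N1=160, relative_b="constant", phi=1.0, Q=1.0, seed=11)
        defaults.update(kwargs)
        return SimScenario(**defaults)
    return make
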