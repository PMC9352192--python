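import numpy as np
import pytest

from stemflux import (
    RateConstants,
    TumorState,
    canonical_case,
    default_initial_state,
)
from stemflux.fixtures import DEFAULT_HORIZON


@pytest.fixture(scope="session")
def x0() -> TumorState:
    return default_initial_state()


@pytest.fixture(scope="session")
def horizon() -> float:
    return DEFAULT_HORIZON


@pytest.fixture(scope="session")
def case_a():
    return canonical_case("A")


@pytest.fixture(scope="session")
def case_pds():
    return {cid: canonical_case(cid).pharmacodynamics for cid in "ABCD"}


def random_rates(rng: np.random.Generator) -> RateConstants:
    """A random valid rate bundle with rates in a physiological band."""
    return RateConstants(
        b_S=rng.uniform(0.01, 0.5),
        b_R=rng.uniform(0.01, 0.5),
        d_S=rng.uniform(0.01, 0.5),
        d_R=rng.uniform(0.01, 0.5),
        k_SR=rng.uniform(0.001, 0.3),
        k_RS=rng.uniform(0.001, 0.3),
    )


def random_state(rng: np.random.Generator, scale: float = 1e9) -> TumorState:
    x1, x2 = rng.uniform(0.0, scale, size=2)
    if x1 + x2 == 0:
        x1 = scale
    return TumorState(x1=x1, x2=x2)
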