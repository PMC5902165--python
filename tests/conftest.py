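import numpy as np
import pytest

from circamyo import curves as cv
from circamyo import simulate as sim


@pytest.fixture(scope="session")
def invitro_small():
    """Small in-vitro simulation shared by curve-level tests."""
    return sim.gen_in_vitro(300, rng_seed=7)


@pytest.fixture(scope="session")
def curveset_small(invitro_small):
    from circamyo.preprocess import average_replicates

    expr, sheet = average_replicates(invitro_small.expr, invitro_small.samples)
    return cv.CurveSet.from_expression(expr, sheet)


@pytest.fixture(scope="session")
def invivo_small():
    """Small in-vivo simulation with a 50/50 rhythmic mix."""
    return sim.gen_in_vivo(120, rhythmic_frac=0.5, rng_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
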