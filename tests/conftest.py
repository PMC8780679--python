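"""Shared fixtures: simulated window sets reused across the suite.

The heavyweight fixtures are session-scoped so each protocol is simulated
once; they use the package's default protocol settings (22 windows full
membrane, 12 per leaflet, 2e5 steps per window).
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import memperm as mp

settings.register_profile("suite", deadline=None, derandomize=True,
                          suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

BULK_BOTH = [(-2.2, -2.0), (2.0, 2.2)]
BULK_OUTER = (-2.2, -2.0)


@pytest.fixture(scope="session")
def flat_pair():
    return mp.make_reference_landscape("flat", D0=0.04)


@pytest.fixture(scope="session")
def flat_traces(flat_pair):
    land, diff = flat_pair
    return mp.simulate_protocol(land, diff, mp.default_protocol())


@pytest.fixture(scope="session")
def gauss_pair():
    return mp.make_reference_landscape("gaussian_barrier", height=10.0,
                                       sigma=0.5, D0=0.04)


@pytest.fixture(scope="session")
def gauss_traces(gauss_pair):
    land, diff = gauss_pair
    return mp.simulate_protocol(land, diff, mp.default_protocol())


@pytest.fixture(scope="session")
def gauss_half_traces(gauss_pair):
    """Outer and inner leaflet protocols sampled independently."""
    land, diff = gauss_pair
    return {
        "outer": mp.simulate_protocol(land, diff, mp.half_protocol("outer")),
        "inner": mp.simulate_protocol(land, diff,
                                      mp.half_protocol("inner", base_seed=3022)),
    }


@pytest.fixture(scope="session")
def membrane_pair():
    return mp.make_reference_landscape("membrane_like")


@pytest.fixture(scope="session")
def membrane_outer_traces(membrane_pair):
    land, diff = membrane_pair
    return mp.simulate_protocol(land, diff, mp.half_protocol("outer"))
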