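import numpy as np
import pytest

import speckletomo as st
from speckletomo.forward import ForwardConfig


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse two-layer phantom with two descending vessels (8 groups)."""
    geometry, strands = st.build_grid_phantom(
        (600.0, 600.0, 400.0),
        10.0,
        [100.0, 250.0],
        (300.0, 600.0),
        [20.0, 15.0],
        descending_radius=12.0,
        descending_depth=350.0,
    )
    return geometry, strands


@pytest.fixture(scope="session")
def fwd_cfg():
    return ForwardConfig()


def random_ensemble(rng, m_max=100, g_max=20):
    """Random photon ensemble: normalized weights, sparse q block, flows."""
    m = int(rng.integers(3, m_max + 1))
    g = int(rng.integers(2, g_max + 1))
    P = rng.uniform(0.1, 1.0, m)
    P /= P.sum()
    Qd = np.where(rng.random((g, m)) < 0.3, rng.normal(0.0, 1.0, (g, m)), 0.0)
    v = rng.uniform(0.3, 5.0, g)  # mm/s
    return P, Qd, v
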