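import numpy as np
import pytest

from premelt.pipeline import calibrate_levels, slab_capillary_pipeline
from premelt.synth import gen_hexagonal, gen_slab


@pytest.fixture(scope="session")
def hex_perfect():
    """Jitter-free triangular lattice (order parameter exactly 1)."""
    return gen_hexagonal(0.52, 0.0, (15.0, 15.0), seed=3)


@pytest.fixture(scope="session")
def slab_frame():
    """One two-phase slab frame with flat ground-truth boundaries."""
    return gen_slab(box=(24.0, 40.0), seed=7)


@pytest.fixture(scope="session")
def synth_levels():
    """Calibrated bulk order-density levels (phi_d, phi_o) for the
    synthetic phases."""
    return calibrate_levels(seed=5)


@pytest.fixture(scope="session")
def slab_recovery_11p5():
    """Full point-cloud stiffness recovery at gamma_true = 11.5 pN.

    Session-scoped because it is the expensive end-to-end run; shared by
    the recovery and interface-statistics tests.
    """
    return slab_capillary_pipeline(11.5, 294.0, seed=20011, n_frames=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
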