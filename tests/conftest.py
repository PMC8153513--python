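import warnings

import numpy as np
import pytest

from vfbayes import build_default_geometry, triangulate
from vfbayes.synthetic_data import reference_truth

warnings.filterwarnings("ignore", message="phase_align")


@pytest.fixture(scope="session")
def geom():
    return build_default_geometry()


@pytest.fixture(scope="session")
def mesh205(geom):
    return triangulate(geom, 205)


@pytest.fixture(scope="session")
def mesh120(geom):
    return triangulate(geom, 120)


@pytest.fixture(scope="session")
def ref_props():
    return reference_truth()


@pytest.fixture(scope="session")
def ref_sim(mesh205, ref_props):
    """Short reference simulation with full history (contact occurs early)."""
    from vfbayes import simulate

    return simulate(ref_props, mesh205, duration_ms=100.0, h_ms=0.05, record_history=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
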