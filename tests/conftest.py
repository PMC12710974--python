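"""Shared fixtures.

The two expensive experiments — the unfold/refold round trip and the fiber
pipeline — run once per session and are shared by the unit and acceptance
tests.  Small meshes for unit tests are built fresh (they are cheap).
"""

import numpy as np
import pytest

from refold.geometry import SlabSpec, make_folded_slab, make_unit_cube
from refold.mesh import compute_node_masses
from refold.pipeline import slab_fiber_pipeline, slab_round_trip


@pytest.fixture(scope="session")
def round_trip():
    """Unfold + refold of the gentle (A/W=0.25) slab, pinned base."""
    return slab_round_trip()


@pytest.fixture(scope="session")
def fiber_run():
    """Fiber pipeline on the deeper-folded (A/W~0.47) slab, free base."""
    return slab_fiber_pipeline(seed=0)


@pytest.fixture(scope="session")
def small_slab():
    """Small folded slab for unit tests (~2k tets)."""
    spec = SlabSpec(extent_x=8.0, extent_y=2.0, depth=2.5,
                    fold_amplitude=0.8, fold_wavelength=4.0,
                    gm_thickness=0.6, h=0.5)
    return compute_node_masses(make_folded_slab(spec))


@pytest.fixture(scope="session")
def small_slab_spec():
    return SlabSpec(extent_x=8.0, extent_y=2.0, depth=2.5,
                    fold_amplitude=0.8, fold_wavelength=4.0,
                    gm_thickness=0.6, h=0.5)


@pytest.fixture()
def unit_cube():
    return compute_node_masses(make_unit_cube(1.0, 0.25))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
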