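"""Shared fixtures: small phantoms reused across test modules.

Session scope keeps the geometry/field/stack construction cost paid once.
"""

import numpy as np
import pytest

from cortexstack import flatstack, phantom


@pytest.fixture(scope="session")
def small_shell():
    """Shell cortex small enough for fast unit tests (10-voxel thickness)."""
    return phantom.make_shell_cortex(r_inner=500.0, r_outer=1000.0,
                                     spacing=50.0)


@pytest.fixture(scope="session")
def small_field(small_shell):
    return flatstack.compute_direction_field(small_shell.cortex)


@pytest.fixture(scope="session")
def small_fs(small_shell, small_field):
    return flatstack.build_flatstack(small_shell.cortex, small_field,
                                     dims=(120, 120, 24))


@pytest.fixture(scope="session")
def slab():
    return phantom.make_slab_cortex(thickness=600.0, lateral=2000.0,
                                    spacing=50.0)


@pytest.fixture(scope="session")
def slab_field(slab):
    return flatstack.compute_direction_field(slab.cortex)


@pytest.fixture(scope="session")
def stpt(small_shell):
    """3-channel tomography phantom on the small shell, with truth."""
    return phantom.make_stpt_phantom(small_shell, injection_radius=300.0,
                                     n_fibers=10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
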