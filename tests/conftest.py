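"""Shared fixtures: fitted beam models and a reusable 5-beam slab plan."""

import numpy as np
import pytest

import emxplan as ex


@pytest.fixture(scope="session")
def curves():
    return ex.default_curves()


@pytest.fixture(scope="session")
def profiles():
    return ex.default_profiles()


@pytest.fixture(scope="session")
def slab_phantom():
    """Water slab with a 4 cm target at 8 cm depth (planning resolution)."""
    return ex.make_selector_phantom(8.0, 4.0, 16.0, spacing=0.5, lateral=12.0)


@pytest.fixture(scope="session")
def slab_iso():
    return (0.0, -8.0, 0.0)


@pytest.fixture(scope="session")
def slab_plan(slab_phantom, slab_iso, curves, profiles):
    """Five equispaced 6 MV beams: DDC matrix, beamlet grids, aperture init."""
    mats, grids = [], []
    for ang in (0.0, 72.0, 144.0, 216.0, 288.0):
        ray = ex.Ray.from_gantry(ang, slab_iso)
        g = ex.make_beamlet_grid(slab_phantom, ray, 6)
        mats.append(ex.compute_ddc(slab_phantom, g, curves[6], profiles[6]))
        grids.append(g)
    A = ex.concat_ddc(mats)
    init = np.concatenate([ex.ciao_init(g, slab_phantom) for g in grids])
    return A, grids, init
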