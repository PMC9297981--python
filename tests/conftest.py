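"""Shared fixtures: small phantoms, reduced geometry, one simulated pair.

Everything is generated at import/run time from seeds; no stored data.
Geometry reductions (fewer views, coarser detector) keep the full physics
pipeline while fitting desk-scale runtimes; distances, arc and the 208-mm
FOV match the full configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from cbctshade.phantom import TissueConfig, generate_phantom, uniform_ellipse_phantom
from cbctshade.simulator import Geometry, PhysicsConfig, forward_project, hu_to_attenuation, simulate_cbct


@pytest.fixture(scope="session")
def desk_geometry() -> Geometry:
    return Geometry(n_views=200, detector_pitch=0.776)


@pytest.fixture(scope="session")
def tissue_config() -> TissueConfig:
    return TissueConfig()


@pytest.fixture(scope="session")
def phantom_300():
    """A 300-mm pelvis phantom deep enough for 8^3 ROI analysis."""
    return generate_phantom(300.0, 10, seed=11, grid_size=384)


@pytest.fixture(scope="session")
def disk_sinogram(desk_geometry):
    """Untruncated uniform 0-HU disk (radius 80 mm) and its sinogram."""
    ph = uniform_ellipse_phantom(160.0, 1, hu=0.0, grid_size=256, ap_ratio=1.0)
    mu = hu_to_attenuation(ph)
    return ph, forward_project(mu.values[0], desk_geometry, 1.0)


@pytest.fixture(scope="session")
def simulated_pair(desk_geometry):
    """One simulated (CBCT, CT) pair from a 300-mm phantom, 3 slices."""
    from cbctshade.pipeline import _center_crop

    ct = generate_phantom(300.0, 3, seed=21, grid_size=384)
    cbct = simulate_cbct(ct, desk_geometry, PhysicsConfig(), seed=21)
    return cbct, _center_crop(ct, 220)
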