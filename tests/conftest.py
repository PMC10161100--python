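"""Shared fixtures: small synthetic grids and phantoms built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gkdosim import (
    CalibrationCurve,
    DensityMaps,
    MaterialTable,
    PhantomSpec,
    build_phantom,
    synthesize_ct,
    build_density_maps,
    default_machine,
)
from gkdosim.dose import water_sphere_density
from gkdosim.grids import UCP, VoxelGrid


@pytest.fixture(scope="session")
def machine():
    return default_machine()


@pytest.fixture(scope="session")
def coarse_labels():
    """Phantom label grid at 2 mm isotropic spacing (fast)."""
    return build_phantom(PhantomSpec(), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def coarse_ct(coarse_labels):
    return synthesize_ct(
        coarse_labels, MaterialTable.default(), CalibrationCurve.default(),
        noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def coarse_maps(coarse_ct):
    return build_density_maps(coarse_ct, CalibrationCurve.default(), pathway="lgp")


@pytest.fixture(scope="session")
def water_maps():
    """Homogeneous water-sphere density maps at 2 mm (reference geometry)."""
    rho = water_sphere_density(spacing=(2.0, 2.0, 2.0))
    return DensityMaps(eta=rho, rho=rho, composition=rho.copy_with(rho.data * 0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_grid(data, origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), origin, spacing)
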