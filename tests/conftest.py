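"""Shared fixtures: small synthetic cells rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ciliaflow import (
    BlurBasis,
    CellGeometry,
    CompartmentState,
    ImagingParams,
    QuantSettings,
    RegionSet,
    quantify_cell,
    render_stack,
    voxelize_cell,
)

#: Coarser lateral sampling used throughout the suite where sub-voxel
#: accuracy is not itself under test; keeps renders fast.
FAST = ImagingParams(voxel_size=(0.3, 0.2, 0.2))


@pytest.fixture(scope="session")
def geometry() -> CellGeometry:
    return CellGeometry()


@pytest.fixture(scope="session")
def voxelized_default(geometry):
    """Default-resolution rasterization (0.3 x 0.1 x 0.1 µm)."""
    return voxelize_cell(geometry, (0.3, 0.1, 0.1))


@pytest.fixture(scope="session")
def voxelized_fast(geometry):
    return voxelize_cell(geometry, FAST.voxel_size)


@pytest.fixture(scope="session")
def basis_fast(voxelized_fast):
    return BlurBasis(voxelized_fast, FAST.sigma_voxels)


@pytest.fixture(scope="session")
def saturated_state() -> CompartmentState:
    """A state with 5% of the reporter in the cilium (post-saturation)."""
    return CompartmentState(
        time=1.5, er=0.12, apical_pm=0.33, basolateral_pm=0.30, cilium=0.05, internalized=0.20
    )


def regions_from_truth(truth) -> RegionSet:
    return RegionSet(
        background={"neighbors": truth.background_region()},
        cell_mask=truth.cell_mask,
    )


def quantify_truth(stack, truth, **settings_overrides):
    settings = QuantSettings(apical_z_um=truth.apical_z_um(), **settings_overrides)
    return quantify_cell(stack, regions_from_truth(truth), settings)


@pytest.fixture(scope="session")
def rendered_saturated(geometry, voxelized_default, saturated_state):
    """One default-resolution noisy render of the saturated-cilium cell."""
    return render_stack(
        geometry, saturated_state, ImagingParams(seed=7), voxelized=voxelized_default
    )
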