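"""Populations of synthetic cells with per-cell biological variability.

Each cell draws an expression level (log-normal, reflecting transient
transfection) and a sorting split ``phi_bl`` (truncated normal around the
population value).  Because every cell conserves mass, a cell sorting more
basolaterally necessarily has less reporter in the apical-plus-ciliary
branch; this anti-correlation is the ground truth behind the opposite-sign
slope structure of ciliary fraction versus apical/basolateral surface
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import CellGeometry, voxelize_cell
from .kinetics import KineticParams, simulate_trafficking
from .render import DEFAULT_CHANNELS, BlurBasis, GroundTruth, ImagingParams, render_stack
from .stack_io import VoxelStack

__all__ = ["PopulationVariability", "generate_population"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class PopulationVariability:
    """Spread of per-cell parameters.

    ``expression_sigma`` is the log-normal shape parameter of the
    expression level (median 1); ``phi_bl_sd`` the standard deviation of
    the per-cell basolateral sorting fraction, truncated to
    [0.05, 0.95].
    """

    expression_sigma: float = 0.4
    phi_bl_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.expression_sigma < 0 or self.phi_bl_sd < 0:
            raise ValueError("variability widths must be >= 0")

    def with_(self, **kwargs) -> "PopulationVariability":
        return replace(self, **kwargs)


def generate_population(
    n_cells: int,
    params: KineticParams = KineticParams(),
    variability: PopulationVariability = PopulationVariability(),
    time: float = 1.0,
    seed: int = 0,
    geometry: CellGeometry = CellGeometry(),
    imaging: ImagingParams = ImagingParams(),
    channels: Sequence[str] = DEFAULT_CHANNELS,
    replicate_id: str = "r0",
) -> list[tuple[VoxelStack, GroundTruth]]:
    """Render ``n_cells`` stacks of one synchronized condition.

    All cells share the geometry (voxelized once) and acquisition
    settings; expression level and ``phi_bl`` are drawn per cell and
    recorded in each cell's :class:`~ciliaflow.render.GroundTruth`.
    ``seed`` fixes both the biological draws and every render's noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    voxelized = voxelize_cell(geometry, imaging.voxel_size)
    basis = BlurBasis(voxelized, imaging.sigma_voxels)

    out: list[tuple[VoxelStack, GroundTruth]] = []
    for i in range(n_cells):
        expr = float(rng.lognormal(mean=0.0, sigma=variability.expression_sigma)) if variability.expression_sigma > 0 else 1.0
        phi = params.phi_bl
        if variability.phi_bl_sd > 0:
            phi = float(np.clip(rng.normal(params.phi_bl, variability.phi_bl_sd), 0.05, 0.95))
        cell_params = params.with_(phi_bl=phi)
        state = simulate_trafficking(cell_params, [time])[0]
        cell_imaging = imaging.with_(seed=int(rng.integers(0, _MAX_SEED)))
        stack, truth = render_stack(
            geometry,
            state,
            cell_imaging,
            channels=channels,
            expression_level=expr,
            voxelized=voxelized,
            blur_basis=basis,
            cell_id=f"cell_{i}",
            phi_bl=phi,
            metadata={"replicate_id": replicate_id},
        )
        out.append((stack, truth))
    return out
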