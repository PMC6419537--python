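"""Image formation: from geometry + compartment state to noisy voxel stacks.

Channels
--------
``gfp``
    Total-reporter fluorescence; every compartment's fractional occupancy is
    spread uniformly over that compartment's voxels, so the integrated
    pre-noise GFP intensity is exactly ``expression_level * photons_per_unit``.
``surface_apical`` / ``surface_basolateral``
    Side-specific surface stain, proportional to the reporter present on that
    membrane domain.  The apical stain covers the ciliary membrane too: the
    cilium is part of the apical surface.
``cilium``
    Ciliary marker (acetylated tubulin / 5HT6-style), independent of the
    reporter; constant density over the cilium.

The optical and camera model: anisotropic Gaussian PSF (unit-sum kernel,
applied before any noise), uniform background, Poisson shot noise on
signal + background, additive Gaussian read noise, clipping at zero and
integer quantization to the requested bit depth.  A fixed seed makes the
output bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import LABELS, CellGeometry, VoxelizedCell, voxelize_cell
from .kinetics import CompartmentState
from .stack_io import VoxelStack

__all__ = [
    "ImagingParams",
    "GroundTruth",
    "BlurBasis",
    "DEFAULT_CHANNELS",
    "FAST_IMAGING",
    "render_stack",
    "render_timelapse",
]

DEFAULT_CHANNELS = ("gfp", "surface_apical", "surface_basolateral", "cilium")


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition model parameters.

    Attributes
    ----------
    voxel_size : (z, y, x) in µm.
    psf_sigma : (lateral, axial) Gaussian PSF sigma in µm; axial >= lateral.
    photons_per_unit : integrated GFP photons for one expression unit.
    marker_photons : integrated ciliary-marker photons per cell.
    stain_gain : surface-stain photons per reporter unit relative to GFP;
        1.0 means equal gain, so a surface-to-total ratio directly reads
        out the surface fraction.
    background_level, read_noise_sd : counts.
    bit_depth : 8 or 16.
    seed : fixes all randomness of one render.
    """

    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)
    psf_sigma: tuple[float, float] = (0.12, 0.35)  # (lateral, axial) µm
    photons_per_unit: float = 2.0e7
    marker_photons: float = 2.0e5
    stain_gain: float = 1.0
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be strictly positive")
        lat, ax = self.psf_sigma
        if ax < lat:
            raise ValueError("axial PSF sigma must be >= lateral sigma")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.photons_per_unit < 0 or self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("photon and noise parameters must be >= 0")

    @property
    def sigma_voxels(self) -> tuple[float, float, float]:
        lat, ax = self.psf_sigma
        dz, dy, dx = self.voxel_size
        return (ax / dz, lat / dy, lat / dx)

    def with_(self, **kwargs) -> "ImagingParams":
        return replace(self, **kwargs)


#: Coarser lateral sampling for population-scale studies (~4x faster renders).
FAST_IMAGING = ImagingParams(voxel_size=(0.3, 0.2, 0.2))


@dataclass
class GroundTruth:
    """Everything the renderer knows about one synthetic cell.

    ``labels`` partitions the stack (outside / intracellular / apical
    membrane / basolateral membrane / cilium / neighbor cell);
    ``pre_noise_totals`` holds the integrated expected signal of every
    rendered channel before background and noise.
    """

    state: CompartmentState
    expression_level: float
    geometry: CellGeometry
    imaging: ImagingParams
    labels: np.ndarray
    cilium_occupancy: np.ndarray
    pre_noise_totals: dict[str, float]
    cell_id: str = "cell_0"
    phi_bl: float | None = None

    @property
    def cell_mask(self) -> np.ndarray:
        return (self.labels >= 1) & (self.labels <= 4)

    @property
    def cilium_mask(self) -> np.ndarray:
        """Voxels that are mostly cilium (occupancy >= 0.5)."""
        return self.labels == LABELS["cilium"]

    @property
    def cilium_support(self) -> np.ndarray:
        """Every voxel containing any ciliary membrane (occupancy > 0)."""
        return self.cilium_occupancy > 0

    def background_region(self) -> np.ndarray:
        """Voxels over non-expressing neighbor cells, for background estimation."""
        return self.labels == LABELS["neighbor_cell"]

    def apical_z_um(self) -> float:
        return self.geometry.apical_z

    def surface_fraction(self, side: str) -> float:
        """True fraction of reporter on the requested surface domain."""
        if side == "apical":
            return self.state.apical_surface
        if side == "basolateral":
            return self.state.basolateral_pm
        raise ValueError(f"unknown side {side!r}")

    def scalars(self) -> dict:
        """JSON-serializable summary (label map excluded)."""
        return {
            "cell_id": self.cell_id,
            "expression_level": self.expression_level,
            "phi_bl": self.phi_bl,
            "state": self.state.as_dict(),
            "pre_noise_totals": self.pre_noise_totals,
            "volume_ratio": self.geometry.volume_ratio(),
        }


def _unit_map(weights: np.ndarray) -> np.ndarray:
    total = float(weights.sum())
    if total <= 0:
        return np.zeros(weights.shape, dtype=np.float64)
    return weights / total


class BlurBasis:
    """PSF-blurred unit-intensity maps, one per cell compartment.

    Image formation is linear, so the expected image of any channel is a
    weighted sum of these four maps.  Building the basis once per
    geometry turns a population render into cheap linear combinations
    plus noise, instead of one PSF convolution per channel per cell.
    """

    def __init__(self, cell: VoxelizedCell, sigma_voxels: tuple[float, float, float]):
        labels = cell.labels
        self.sigma_voxels = tuple(sigma_voxels)
        self.shape = labels.shape
        self.maps = {
            "interior": self._blur(_unit_map(labels == LABELS["intracellular"])),
            "apical": self._blur(_unit_map(labels == LABELS["apical_membrane"])),
            "basolateral": self._blur(_unit_map(labels == LABELS["basolateral_membrane"])),
            "cilium": self._blur(_unit_map(cell.cilium_occupancy.astype(np.float64))),
        }

    def _blur(self, img: np.ndarray) -> np.ndarray:
        return gaussian_filter(img, sigma=self.sigma_voxels, mode="constant")

    def combine(self, amounts: dict[str, float]) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.float64)
        for comp, amount in amounts.items():
            if amount:
                out += amount * self.maps[comp]
        return out


def _channel_amounts(
    state: CompartmentState,
    imaging: ImagingParams,
    expression_level: float,
    channel: str,
) -> dict[str, float]:
    """Expected integrated photons of each compartment in one channel."""
    gfp_total = expression_level * imaging.photons_per_unit
    if channel == "gfp":
        return {
            "interior": (state.er + state.internalized) * gfp_total,
            "apical": state.apical_pm * gfp_total,
            "basolateral": state.basolateral_pm * gfp_total,
            "cilium": state.cilium * gfp_total,
        }
    if channel == "surface_apical":
        # the apical surface stain reaches the ciliary membrane too
        return {
            "apical": state.apical_pm * gfp_total * imaging.stain_gain,
            "cilium": state.cilium * gfp_total * imaging.stain_gain,
        }
    if channel == "surface_basolateral":
        return {"basolateral": state.basolateral_pm * gfp_total * imaging.stain_gain}
    if channel == "cilium":
        return {"cilium": imaging.marker_photons}
    raise ValueError(f"unknown channel {channel!r}")


def render_stack(
    geometry: CellGeometry,
    state: CompartmentState,
    imaging: ImagingParams,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    expression_level: float = 1.0,
    apply_noise: bool = True,
    voxelized: VoxelizedCell | None = None,
    blur_basis: BlurBasis | None = None,
    cell_id: str = "cell_0",
    phi_bl: float | None = None,
    metadata: Mapping[str, object] | None = None,
) -> tuple[VoxelStack, GroundTruth]:
    """Render one synthetic multi-channel stack plus its ground truth.

    Parameters
    ----------
    voxelized, blur_basis : optional pre-rasterized geometry and
        pre-blurred compartment maps; pass them when rendering many
        cells of identical geometry to skip re-voxelization and
        re-convolution.
    apply_noise : when False the returned stack is the expected photon
        image plus background as float64 (no Poisson/read noise, no
        quantization); the PSF is applied either way.

    Returns
    -------
    (VoxelStack, GroundTruth)
    """
    if voxelized is None:
        voxelized = voxelize_cell(geometry, imaging.voxel_size)
    elif voxelized.voxel_size != tuple(imaging.voxel_size):
        raise ValueError("voxelized geometry and imaging voxel_size disagree")
    if blur_basis is None:
        blur_basis = BlurBasis(voxelized, imaging.sigma_voxels)
    elif blur_basis.sigma_voxels != imaging.sigma_voxels or blur_basis.shape != voxelized.shape:
        raise ValueError("blur_basis does not match this geometry/imaging combination")

    amounts = {name: _channel_amounts(state, imaging, expression_level, name) for name in channels}
    pre_totals = {name: float(sum(a.values())) for name, a in amounts.items()}

    rng = np.random.default_rng(imaging.seed)
    planes = []
    for name in channels:
        img = blur_basis.combine(amounts[name])
        img = img + imaging.background_level
        if apply_noise:
            noisy = rng.poisson(img).astype(np.float64)
            noisy += rng.normal(0.0, imaging.read_noise_sd, size=img.shape)
            maxval = 2**imaging.bit_depth - 1
            dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
            img = np.clip(np.rint(noisy), 0, maxval).astype(dtype)
        planes.append(img)

    meta = {
        "release_time_h": state.time,
        "stained_side": _stained_side(channels),
        "replicate_id": "sim",
        "seed": imaging.seed,
        "cell_id": cell_id,
    }
    if metadata:
        meta.update(metadata)
    stack = VoxelStack(
        data=np.stack(planes),
        channel_names=tuple(channels),
        voxel_size=tuple(imaging.voxel_size),
        metadata=meta,
    )
    truth = GroundTruth(
        state=state,
        expression_level=expression_level,
        geometry=geometry,
        imaging=imaging,
        labels=voxelized.labels,
        cilium_occupancy=voxelized.cilium_occupancy,
        pre_noise_totals=pre_totals,
        cell_id=cell_id,
        phi_bl=phi_bl,
    )
    return stack, truth


def render_timelapse(
    geometry: CellGeometry,
    states: Sequence[CompartmentState],
    imaging: ImagingParams,
    channels: Sequence[str] = ("gfp", "cilium"),
    expression_level: float = 1.0,
    plane_z_um: float | None = None,
    seed: int | None = None,
    apply_noise: bool = True,
) -> tuple[list[VoxelStack], np.ndarray]:
    """Render a live-imaging time lapse from a state trajectory.

    One frame per state, each with fresh noise.  With ``plane_z_um`` set
    (or by default, mid-cilium) frames are single confocal planes
    (depth-1 stacks), as in spinning-disc live imaging; pass
    ``plane_z_um = -1`` for full 3D frames.  Returns the frames plus a
    static empty background region matching the frame shape.
    """
    if plane_z_um is None:
        plane_z_um = (geometry.apical_z + geometry.cilium_tip_z) / 2.0
    base_seed = imaging.seed if seed is None else seed
    voxelized = voxelize_cell(geometry, imaging.voxel_size)
    basis = BlurBasis(voxelized, imaging.sigma_voxels)
    frames: list[VoxelStack] = []
    for i, state in enumerate(states):
        stack, _ = render_stack(
            geometry,
            state,
            imaging.with_(seed=(base_seed + i) % (2**31 - 1)),
            channels=channels,
            expression_level=expression_level,
            apply_noise=apply_noise,
            voxelized=voxelized,
            blur_basis=basis,
            metadata={"time_min": state.time * 60.0},
        )
        if plane_z_um >= 0:
            zi = min(int(plane_z_um / imaging.voxel_size[0]), stack.shape[0] - 1)
            stack = VoxelStack(
                data=stack.data[:, zi : zi + 1],
                channel_names=stack.channel_names,
                voxel_size=stack.voxel_size,
                metadata=stack.metadata,
            )
        frames.append(stack)

    shape = frames[0].shape
    background = np.zeros(shape, dtype=bool)
    # corner block well away from cell and cilium
    background[:, : max(1, shape[1] // 8), : max(1, shape[2] // 8)] = True
    return frames, background


def _stained_side(channels: Sequence[str]) -> str:
    has_ap = "surface_apical" in channels
    has_bl = "surface_basolateral" in channels
    if has_ap and has_bl:
        return "both"
    if has_ap:
        return "apical"
    if has_bl:
        return "basolateral"
    return "none"
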