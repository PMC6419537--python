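"""Per-cell quantification: background, cilium segmentation, QC, MCC, ratios.

The central statistic is the Manders' co-localization coefficient

    MCC = (sum of reporter signal in ciliary-marker-positive voxels)
          / (sum of reporter signal in all reporter-positive voxels),

i.e. the fraction of the cell's total reporter residing in the primary
cilium.  "Reporter-positive" means above the (clipped) background-subtracted
zero level within the cell region; an optional extra intensity threshold is
exposed for stricter definitions.  The companion statistic is the
surface-to-total ratio: summed side-specific surface-stain signal divided by
summed total-reporter signal over the same cell region.

Quality control mirrors standard practice for co-localization at the
resolution limit: only cells with a clearly protruding, not sharply tilted
cilium are assigned an MCC; excluded cells keep their surface ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .stack_io import RegionSet, VoxelStack

__all__ = [
    "QuantSettings",
    "CellQuantification",
    "QuantResult",
    "subtract_background",
    "segment_cilium",
    "cilium_qc",
    "manders_mcc",
    "surface_total_ratio",
    "quantify_cell",
]


@dataclass(frozen=True)
class QuantSettings:
    """Tunable knobs of the per-cell quantification.

    Attributes
    ----------
    gfp_channel, marker_channel : channel names in the stack.
    surface_channels : mapping side -> channel name; sides missing from
        the stack are skipped.
    marker_threshold : absolute threshold for the ciliary marker; None
        selects Otsu's threshold on the positive voxels.
    mask_dilation_um : isotropic dilation of the segmented cilium mask
        before summing reporter signal, to recapture PSF-blurred ciliary
        signal that falls just outside the marker core.
    gfp_threshold : extra intensity threshold defining "reporter
        positive" voxels in the MCC denominator (0 = any signal above
        the subtracted background).
    cell_margin_um : margin added around the cell mask before summing
        intensities, so blurred membrane signal is not clipped at the
        cell outline.
    tilt_max_deg, min_protrusion_um : cilium QC limits.
    apical_z_um : z of the apical face; None estimates it as the 95th
        percentile of the cell-mask z distribution.
    """

    gfp_channel: str = "gfp"
    marker_channel: str = "cilium"
    surface_channels: tuple[tuple[str, str], ...] = (
        ("apical", "surface_apical"),
        ("basolateral", "surface_basolateral"),
    )
    marker_threshold: float | None = None
    mask_dilation_um: float = 0.25
    gfp_threshold: float = 0.0
    cell_margin_um: float = 1.0
    tilt_max_deg: float = 60.0
    min_protrusion_um: float = 1.0
    apical_z_um: float | None = None

    def with_(self, **kwargs) -> "QuantSettings":
        return replace(self, **kwargs)


@dataclass
class CellQuantification:
    """One row of the per-cell output table (one side per row)."""

    cell_id: str
    release_time_h: float
    side: str  # "apical" or "basolateral"
    surface_ratio: float | None
    mcc: float | None
    cilium_voxels: int
    qc_pass: bool
    qc_reason: str = ""
    replicate_id: str = "r0"


@dataclass
class QuantResult:
    """Records for one cell plus full provenance of the computation."""

    records: list[CellQuantification]
    cilium_mask: np.ndarray
    cell_mask: np.ndarray
    provenance: dict


def subtract_background(stack: VoxelStack, regions: RegionSet) -> VoxelStack:
    """Subtract a per-channel scalar background estimated over empty regions.

    The background of each channel is its mean over the union of the
    background regions (non-expressing cells); negative results are
    clipped to zero.  Estimates are recorded in the stack metadata under
    ``background_counts``.
    """
    regions.validate_against(stack)
    bg_mask = regions.combined_background()
    if regions.cell_mask is not None and np.any(bg_mask & regions.cell_mask):
        warnings.warn(
            "background region overlaps the expressing cell; background may be "
            "overestimated",
            stacklevel=2,
        )
    data = stack.data.astype(np.float64)
    levels = {}
    for i, name in enumerate(stack.channel_names):
        level = float(data[i][bg_mask].mean())
        levels[name] = level
        data[i] = np.clip(data[i] - level, 0.0, None)
    return stack.with_data(data, background_counts=levels)


def segment_cilium(
    marker: np.ndarray,
    voxel_size: tuple[float, float, float],
    apical_z_um: float,
    threshold: float | None = None,
) -> np.ndarray:
    """Segment the primary cilium in a background-subtracted marker channel.

    The threshold (Otsu on positive voxels unless given) binarizes the
    channel; of the resulting connected components only those protruding
    above the apical reference plane are candidates, and the largest one
    is returned (ties broken by protrusion height, then brightness).
    An all-empty mask is a valid outcome.
    """
    marker = np.asarray(marker, dtype=np.float64)
    if threshold is None:
        positive = marker[marker > 0]
        if positive.size < 2 or float(positive.max()) == float(positive.min()):
            return np.zeros(marker.shape, dtype=bool)
        threshold = float(threshold_otsu(positive))
    binary = marker > threshold
    if not binary.any():
        return np.zeros(marker.shape, dtype=bool)

    comps, n = cc_label(binary, return_num=True, connectivity=3)
    dz = voxel_size[0]
    best = None  # (size, protrusion, brightness, id)
    for cid in range(1, n + 1):
        comp = comps == cid
        zs = np.nonzero(comp)[0]
        top_z = (zs.max() + 0.5) * dz
        if top_z <= apical_z_um:
            continue  # does not protrude: intracellular marker signal
        key = (int(comp.sum()), top_z - apical_z_um, float(marker[comp].sum()))
        if best is None or key > best[0]:
            best = (key, cid)
    if best is None:
        return np.zeros(marker.shape, dtype=bool)
    return comps == best[1]


def cilium_qc(
    mask: np.ndarray,
    apical_z_um: float,
    voxel_size: tuple[float, float, float],
    tilt_max_deg: float = 60.0,
    min_protrusion_um: float = 1.0,
) -> tuple[bool, str]:
    """Decide whether a segmented cilium is usable for co-localization.

    Passes iff the mask is non-empty, its principal axis is within
    ``tilt_max_deg`` of the z-axis, and it extends at least
    ``min_protrusion_um`` above the apical plane.  A cilium lying flat in
    the apical plane fails as "sharply tilted": its co-localization with
    the surrounding apical membrane cannot be resolved.
    """
    if not mask.any():
        return False, "no cilium detected"
    coords = np.argwhere(mask).astype(np.float64)
    coords = (coords + 0.5) * np.asarray(voxel_size)
    top = coords[:, 0].max()
    protrusion = top - apical_z_um
    tilt = _principal_axis_tilt_deg(coords)
    if tilt > tilt_max_deg:
        return False, f"sharply tilted ({tilt:.0f} deg from z-axis)"
    if protrusion < min_protrusion_um:
        return False, f"insufficient protrusion ({protrusion:.2f} um above apical plane)"
    return True, ""


def _principal_axis_tilt_deg(coords_um: np.ndarray) -> float:
    if len(coords_um) < 3:
        return 0.0
    centered = coords_um - coords_um.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    cos_tilt = min(1.0, abs(float(axis[0])) / (np.linalg.norm(axis) + 1e-300))
    return math.degrees(math.acos(cos_tilt))


def manders_mcc(
    gfp: np.ndarray,
    cilium_mask: np.ndarray,
    cell_mask: np.ndarray | None = None,
    gfp_threshold: float = 0.0,
) -> float:
    """Fraction of the reporter signal residing in the ciliary mask.

    ``gfp`` must be background-subtracted.  The denominator sums the
    reporter over all reporter-positive voxels (optionally restricted to
    ``cell_mask``); the numerator sums it over the reporter-positive
    voxels inside ``cilium_mask``.  Always in [0, 1].
    """
    gfp = np.asarray(gfp, dtype=np.float64)
    support = gfp > gfp_threshold
    if cell_mask is not None:
        support &= cell_mask
    denom = float(gfp[support].sum())
    if denom <= 0:
        raise ValueError("total reporter signal is zero; MCC undefined")
    numer = float(gfp[support & cilium_mask].sum())
    return numer / denom


def surface_total_ratio(
    surface: np.ndarray,
    gfp: np.ndarray,
    cell_mask: np.ndarray,
) -> float:
    """Side-specific surface-stain signal over total reporter signal.

    Both channels must be background-subtracted and are summed over the
    same cell region.  Not capped at 1: the two channels have
    independent gains, so only within-series comparisons are meaningful.
    """
    if not cell_mask.any():
        raise ValueError("cell_mask is empty")
    denom = float(np.asarray(gfp, dtype=np.float64)[cell_mask].sum())
    if denom <= 0:
        raise ValueError("total reporter signal is zero; ratio undefined")
    numer = float(np.asarray(surface, dtype=np.float64)[cell_mask].sum())
    return max(numer, 0.0) / denom


def _dilate_um(mask: np.ndarray, radius_um: float, voxel_size) -> np.ndarray:
    if radius_um <= 0 or not mask.any():
        return mask
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return dist <= radius_um


def quantify_cell(
    stack: VoxelStack,
    regions: RegionSet,
    settings: QuantSettings = QuantSettings(),
) -> QuantResult:
    """Run the full per-cell quantification chain on one stack.

    Background subtraction -> cilium segmentation -> QC -> MCC (QC-passing
    cells only) and surface-to-total ratio per stained side present in the
    stack.  Every intermediate value lands in the provenance dict.
    """
    if regions.cell_mask is None:
        raise ValueError("quantification requires a cell mask (RegionSet.cell_mask)")
    for name in (settings.gfp_channel, settings.marker_channel):
        if not stack.has_channel(name):
            raise KeyError(f"stack has no channel {name!r}; channels: {stack.channel_names}")

    sub = subtract_background(stack, regions)
    gfp = sub.channel(settings.gfp_channel)
    marker = sub.channel(settings.marker_channel)

    # Unclipped background-subtracted channels for the intensity sums:
    # clipping at zero would add a positive noise pedestal over the many
    # near-empty voxels of the cell region and bias the ratios upward,
    # whereas the signed residuals cancel in expectation.
    bg = sub.metadata["background_counts"]
    raw = stack.data.astype(np.float64)
    unclipped = {
        name: raw[i] - bg[name] for i, name in enumerate(stack.channel_names)
    }

    cell_mask = _dilate_um(regions.cell_mask, settings.cell_margin_um, stack.voxel_size)

    if settings.apical_z_um is not None:
        apical_z = settings.apical_z_um
    else:
        zs = (np.nonzero(regions.cell_mask)[0] + 0.5) * stack.voxel_size[0]
        apical_z = float(np.percentile(zs, 95.0))

    core_mask = segment_cilium(marker, stack.voxel_size, apical_z, settings.marker_threshold)
    qc_pass, qc_reason = cilium_qc(
        core_mask,
        apical_z,
        stack.voxel_size,
        tilt_max_deg=settings.tilt_max_deg,
        min_protrusion_um=settings.min_protrusion_um,
    )
    cilium_mask = _dilate_um(core_mask, settings.mask_dilation_um, stack.voxel_size)

    mcc: float | None = None
    if qc_pass:
        mcc = manders_mcc(gfp, cilium_mask, cell_mask, settings.gfp_threshold)

    meta = stack.metadata
    cell_id = str(meta.get("cell_id", "cell_0"))
    replicate_id = str(meta.get("replicate_id", "r0"))
    release_time = float(meta.get("release_time_h", float("nan")))

    records: list[CellQuantification] = []
    ratios: dict[str, float] = {}
    for side, chan in settings.surface_channels:
        if not stack.has_channel(chan):
            continue
        ratio = surface_total_ratio(unclipped[chan], unclipped[settings.gfp_channel], cell_mask)
        ratios[side] = ratio
        records.append(
            CellQuantification(
                cell_id=cell_id,
                replicate_id=replicate_id,
                release_time_h=release_time,
                side=side,
                surface_ratio=ratio,
                mcc=mcc,
                cilium_voxels=int(core_mask.sum()),
                qc_pass=qc_pass,
                qc_reason=qc_reason,
            )
        )
    if not records:  # no surface channel at all: still report the MCC row
        records.append(
            CellQuantification(
                cell_id=cell_id,
                replicate_id=replicate_id,
                release_time_h=release_time,
                side="none",
                surface_ratio=None,
                mcc=mcc,
                cilium_voxels=int(core_mask.sum()),
                qc_pass=qc_pass,
                qc_reason=qc_reason,
            )
        )

    provenance = {
        "background_counts": sub.metadata.get("background_counts"),
        "apical_z_um": apical_z,
        "marker_threshold": (
            settings.marker_threshold if settings.marker_threshold is not None else "otsu"
        ),
        "cilium_core_voxels": int(core_mask.sum()),
        "cilium_mask_voxels": int(cilium_mask.sum()),
        "mask_dilation_um": settings.mask_dilation_um,
        "cell_margin_um": settings.cell_margin_um,
        "qc_pass": qc_pass,
        "qc_reason": qc_reason,
        "mcc": mcc,
        "surface_ratios": ratios,
        "settings": {
            "tilt_max_deg": settings.tilt_max_deg,
            "min_protrusion_um": settings.min_protrusion_um,
            "gfp_threshold": settings.gfp_threshold,
        },
    }
    return QuantResult(
        records=records,
        cilium_mask=cilium_mask,
        cell_mask=cell_mask,
        provenance=provenance,
    )
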