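"""Reading and writing the formats the pipeline touches.

Stacks are OME-TIFF (preferred) or plain multi-page TIFF; axis order is
``(channel, z, y, x)``.  Every stack written by this package carries its
voxel size in the OME metadata and a JSON sidecar (``<stem>.json``) with the
channel names, acquisition metadata and, for synthetic data, the ground-truth
scalars.  Tabular outputs are UTF-8 CSV with a header; per-cell provenance is
JSON.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelStack",
    "RegionSet",
    "DEFAULT_VOXEL_SIZE",
    "read_stack",
    "write_stack",
    "write_quant_table",
    "read_quant_table",
]

#: Fallback (z, y, x) voxel size in µm when a file carries no calibration.
DEFAULT_VOXEL_SIZE = (0.3, 0.1, 0.1)

#: Stable column order of the per-cell quantification table.
QUANT_COLUMNS = [
    "cell_id",
    "replicate_id",
    "release_time_h",
    "side",
    "surface_ratio",
    "mcc",
    "cilium_voxels",
    "qc_pass",
    "qc_reason",
]


@dataclass
class VoxelStack:
    """Multi-channel 3D intensity grid with voxel-size metadata.

    ``data`` has shape ``(n_channels, nz, ny, nx)``; ``voxel_size`` is
    ``(z, y, x)`` in µm.  ``metadata`` carries acquisition context
    (release time, stained side, replicate ID, ...).
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C, Z, Y, X), got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels in data but "
                f"{len(self.channel_names)} channel names: {self.channel_names}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be strictly positive")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (z, y, x)."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def with_data(self, data: np.ndarray, **meta_updates) -> "VoxelStack":
        md = dict(self.metadata)
        md.update(meta_updates)
        return VoxelStack(
            data=data,
            channel_names=self.channel_names,
            voxel_size=self.voxel_size,
            metadata=md,
        )


@dataclass
class RegionSet:
    """Named voxel masks: background regions and an optional cell outline."""

    background: dict[str, np.ndarray] = field(default_factory=dict)
    cell_mask: np.ndarray | None = None

    def validate_against(self, stack: VoxelStack) -> None:
        for name, mask in self.background.items():
            if mask.shape != stack.shape:
                raise ValueError(
                    f"background region {name!r} shape {mask.shape} does not match "
                    f"stack shape {stack.shape}"
                )
            if not mask.any():
                raise ValueError(f"background region {name!r} is empty")
        if self.cell_mask is not None and self.cell_mask.shape != stack.shape:
            raise ValueError("cell_mask shape does not match stack shape")

    def combined_background(self) -> np.ndarray:
        if not self.background:
            raise ValueError("RegionSet has no background regions")
        masks = list(self.background.values())
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out


def write_stack(stack: VoxelStack, path: str | Path, ground_truth_scalars: dict | None = None) -> None:
    """Write an OME-TIFF plus a JSON sidecar with metadata / ground truth."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    data = stack.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    sidecar = {
        "channel_names": list(stack.channel_names),
        "voxel_size_um_zyx": list(stack.voxel_size),
        "metadata": _jsonable(stack.metadata),
    }
    if ground_truth_scalars is not None:
        sidecar["ground_truth"] = _jsonable(ground_truth_scalars)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
) -> VoxelStack:
    """Read a TIFF/OME-TIFF stack into a :class:`VoxelStack`.

    The JSON sidecar written by :func:`write_stack` is honoured if
    present; otherwise voxel size is taken from the OME metadata, and if
    neither exists the documented default (0.3, 0.1, 0.1) µm is used
    with a warning.  A 2-D single-plane image is promoted to a
    one-channel, depth-1 stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            ome_xml = tif.ome_metadata
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"cannot read TIFF file {path}: {exc}") from exc

    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None

    voxel_size = None
    names = list(channel_names) if channel_names is not None else None
    metadata: dict = {}
    if sidecar:
        voxel_size = tuple(sidecar.get("voxel_size_um_zyx", ())) or None
        metadata = sidecar.get("metadata", {})
        if names is None and "channel_names" in sidecar:
            names = list(sidecar["channel_names"])
    if voxel_size is None and ome_xml:
        voxel_size = _voxel_size_from_ome(ome_xml)
        if names is None:
            names = _channel_names_from_ome(ome_xml)
    if voxel_size is None:
        warnings.warn(
            f"{path.name}: no voxel-size metadata found; assuming default "
            f"{DEFAULT_VOXEL_SIZE} µm (z, y, x)",
            stacklevel=2,
        )
        voxel_size = DEFAULT_VOXEL_SIZE

    data = _normalize_axes(data, names)
    if names is None:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path.name}: file has {data.shape[0]} channels but "
            f"{len(names)} channel names were given: {names}"
        )
    return VoxelStack(
        data=data,
        channel_names=tuple(names),
        voxel_size=tuple(float(v) for v in voxel_size),
        metadata=metadata,
    )


def _normalize_axes(data: np.ndarray, names: Sequence[str] | None) -> np.ndarray:
    if data.ndim == 2:  # single plane -> one channel, depth 1
        return data[None, None, :, :]
    if data.ndim == 3:
        # (C, Y, X) if the leading axis matches the channel count, else (Z, Y, X)
        if names is not None and data.shape[0] == len(names):
            return data[:, None, :, :]
        return data[None, :, :, :]
    if data.ndim == 4:
        return data
    raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")


def _voxel_size_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    try:
        d = tifffile.xml2dict(ome_xml)
        px = d["OME"]["Image"]["Pixels"]
        if isinstance(px, list):
            px = px[0]
        return (
            float(px["PhysicalSizeZ"]),
            float(px["PhysicalSizeY"]),
            float(px["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def _channel_names_from_ome(ome_xml: str) -> list[str] | None:
    try:
        d = tifffile.xml2dict(ome_xml)
        img = d["OME"]["Image"]
        if isinstance(img, list):
            img = img[0]
        chans = img["Pixels"]["Channel"]
        if isinstance(chans, dict):
            chans = [chans]
        names = [c.get("Name") for c in chans]
        if all(n for n in names):
            return [str(n) for n in names]
    except (KeyError, TypeError):
        pass
    return None


def write_quant_table(records: Sequence, path: str | Path) -> None:
    """Write per-cell quantifications as CSV, one row per cell/side.

    Cells that failed cilium QC keep their row; the ``mcc`` field is
    left empty and ``qc_reason`` says why.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
        rows.append({col: d.get(col) for col in QUANT_COLUMNS})
    df = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_quant_table(path: str | Path):
    """Read a quantification CSV back into CellQuantification records."""
    from .quant import CellQuantification  # local import: avoid cycle

    df = pd.read_csv(path, encoding="utf-8")
    records = []
    for _, row in df.iterrows():
        records.append(
            CellQuantification(
                cell_id=str(row["cell_id"]),
                replicate_id=str(row["replicate_id"]),
                release_time_h=float(row["release_time_h"]),
                side=str(row["side"]),
                surface_ratio=_opt_float(row["surface_ratio"]),
                mcc=_opt_float(row["mcc"]),
                cilium_voxels=int(row["cilium_voxels"]),
                qc_pass=_as_bool(row["qc_pass"]),
                qc_reason=("" if pd.isna(row["qc_reason"]) else str(row["qc_reason"])),
            )
        )
    return records


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
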