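"""Reproducible run configuration: YAML in, validated domain objects out.

A :class:`RunConfig` gathers every tunable of a pipeline run — kinetic and
imaging parameters, geometry, per-cell variability, quantification settings,
the simulated experiment layout, and the seed.  Validation is explicit and
eager: unknown keys and out-of-range values fail before any computation, and
the fully-resolved configuration (defaults included) is what the pipeline
writes into its manifest, so "default" is never ambiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import CellGeometry
from .kinetics import KineticParams
from .population import PopulationVariability
from .quant import QuantSettings
from .render import DEFAULT_CHANNELS, ImagingParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("ciliaflow_out")
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    kinetics: KineticParams = field(default_factory=KineticParams)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    variability: PopulationVariability = field(default_factory=PopulationVariability)
    quant: QuantSettings = field(default_factory=QuantSettings)
    n_cells: int = 10
    times_h: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("simulate.n_cells must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("simulate.replicates must be >= 1")
        if not self.times_h or any(t < 0 for t in self.times_h):
            raise ConfigError("simulate.times_h must be non-empty and non-negative")
        if not self.channels:
            raise ConfigError("channels must be non-empty")
        unknown = set(self.channels) - set(DEFAULT_CHANNELS)
        if unknown:
            raise ConfigError(
                f"unknown channels {sorted(unknown)}; allowed: {list(DEFAULT_CHANNELS)}"
            )
        if "gfp" not in self.channels or "cilium" not in self.channels:
            raise ConfigError("channels must include 'gfp' and 'cilium'")

    def resolved(self) -> dict:
        """Every parameter of this run, defaults included (for the manifest)."""

        def dump(obj):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}

        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "channels": list(self.channels),
            "kinetics": dump(self.kinetics),
            "geometry": dump(self.geometry),
            "imaging": dump(self.imaging),
            "variability": dump(self.variability),
            "quant": dump(self.quant),
            "simulate": {
                "n_cells": self.n_cells,
                "times_h": list(self.times_h),
                "replicates": self.n_replicates,
            },
        }


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, Path):
        return str(v)
    return v


_SECTION_TYPES = {
    "kinetics": KineticParams,
    "geometry": CellGeometry,
    "imaging": ImagingParams,
    "variability": PopulationVariability,
    "quant": QuantSettings,
}
_TOP_KEYS = {"seed", "output_dir", "channels", "simulate", *_SECTION_TYPES}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``overrides`` (e.g. a CLI ``--seed``) win over the file; with no
    path, the documented defaults are used.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}")

    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])
    if "channels" in raw:
        kwargs["channels"] = tuple(raw["channels"])

    for section, cls in _SECTION_TYPES.items():
        if section not in raw:
            continue
        body = raw[section] or {}
        if not isinstance(body, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(body) - allowed
        if bad:
            raise ConfigError(
                f"unknown keys {sorted(bad)} in section {section!r}; allowed: {sorted(allowed)}"
            )
        body = {k: _coerce(v) for k, v in body.items()}
        try:
            kwargs[section] = cls(**body)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid {section} configuration: {exc}") from exc

    sim = raw.get("simulate", {}) or {}
    if not isinstance(sim, dict):
        raise ConfigError("section 'simulate' must be a mapping")
    bad = set(sim) - {"n_cells", "times_h", "replicates"}
    if bad:
        raise ConfigError(f"unknown keys {sorted(bad)} in section 'simulate'")
    if "n_cells" in sim:
        kwargs["n_cells"] = int(sim["n_cells"])
    if "times_h" in sim:
        kwargs["times_h"] = tuple(float(t) for t in sim["times_h"])
    if "replicates" in sim:
        kwargs["n_replicates"] = int(sim["replicates"])

    try:
        return RunConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _coerce(v):
    if isinstance(v, list):
        return tuple(_coerce(x) for x in v)
    return v
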