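"""Run configuration: one YAML-serializable object holding every threshold.

The config is validated on construction and a verbatim snapshot is written
into every output directory so that any number in any output table can be
traced back to the exact settings that produced it.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .synthgen.types import ConfigError, PlacementModel, ScopeConfig

#: documented valid ranges for the analysis thresholds
_RANGES = {
    "dip_depth_min": (0.0, 1.0),
    "c_polar": (0.0, 0.5),
    "v_mini": (0.0, 0.25),
    "occupancy_tolerance": (0.0, 1.0),
    "arrival_theta": (0.0, 1.0),
    "constriction_min_depth": (0.0, 1.0),
    "nucleoid_extent_fraction": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, in one serializable object."""

    seed: int = 0
    out_dir: str = "divplane_out"
    # channel-name map: logical name -> name in the input data
    channels: dict[str, str] = field(
        default_factory=lambda: {
            c: c for c in ("cyto", "dapi", "ring", "matp", "phase")
        }
    )
    # synthetic generation
    scope: dict[str, Any] = field(default_factory=dict)
    placement: dict[str, Any] = field(default_factory=dict)
    n_cells: int = 150
    n_divisions: int = 600
    n_timelapse_cells: int = 8
    t_d_frames: float = 48.0
    t_matp_fraction: float = 0.2
    lag_fraction: float = 0.12
    frame_interval_min: float = 2.5
    # analysis thresholds
    dip_depth_min: float = 0.10
    c_polar: float = 0.30
    v_mini: float = 0.10
    occupancy_tolerance: float = 0.25
    arrival_theta: float = 0.5
    arrival_k: int = 2
    length_bin_um: float = 0.25
    lag_bin: float = 0.05
    constriction_min_depth: float = 0.15
    nucleoid_extent_fraction: float = 0.20
    half_width_um: float = 0.35

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ConfigError(
                    f"{name}={v} outside its documented range ({lo}, {hi})"
                )
        if self.arrival_k < 1:
            raise ConfigError("arrival_k must be >= 1")
        for name in ("length_bin_um", "lag_bin", "half_width_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("n_cells", "n_divisions", "n_timelapse_cells"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        missing = {"cyto", "ring"} - set(self.channels)
        if missing:
            raise ConfigError(f"channel map lacks required names: {missing}")

    # -- factories -----------------------------------------------------------

    def scope_config(self, seed: Optional[int] = None) -> ScopeConfig:
        kw = dict(self.scope)
        if seed is not None:
            kw["rng_seed"] = seed
        return ScopeConfig(**kw)

    def placement_model(self) -> PlacementModel:
        return PlacementModel(**self.placement)

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
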