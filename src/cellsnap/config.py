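"""Run configuration and voxel geometry.

The refractive-index (RI) tomograms this package consumes are exported as
uint16 TIFF stacks holding ``round(RI * ri_scale)``.  Neither the scale
factor nor the medium RI can be recovered from the data alone, so both are
mandatory configuration: a silently wrong scale corrupts every downstream
dry-mass value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

#: Specific refraction increment expressed as reciprocal density,
#: volume of dry material per picogram (um^3 / pg).
DEFAULT_ALPHA = 0.19

#: RI of typical aqueous imaging medium.
DEFAULT_MEDIUM_RI = 1.337

#: Stored integer = round(RI * ri_scale); 10^4 is the common convention.
DEFAULT_RI_SCALE = 10000

_VALID_CONN_2D = (4, 8)
_VALID_CONN_3D = (6, 18, 26)


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel pitches in micrometres.

    Parameters
    ----------
    dx, dy : float
        Lateral pitches (um), typically equal.
    dz : float
        Axial pitch (um); axial resolution of tomographic systems is
        usually coarser than lateral.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ConfigError(f"voxel pitch {name}={v!r} must be finite and > 0")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.dx * self.dy * self.dz

    @property
    def pixel_area(self) -> float:
        """Lateral pixel area dx*dy in um^2."""
        return self.dx * self.dy


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters.

    ``z_floor_fraction`` is the normalized per-slice voxel-count level at
    which the cell bottom is declared, cutting off dish-floor roughness.
    ``alpha`` converts the integrated optical path difference into dry
    mass (um^3 per pg).
    """

    ri_scale: int = DEFAULT_RI_SCALE
    medium_ri: float = DEFAULT_MEDIUM_RI
    z_floor_fraction: float = 0.5
    connectivity_2d: int = 8
    connectivity_3d: int = 26
    alpha: float = DEFAULT_ALPHA
    geometry: VoxelGeometry = field(default_factory=lambda: VoxelGeometry(0.1, 0.1, 0.2))

    def __post_init__(self) -> None:
        if not (isinstance(self.ri_scale, int) and self.ri_scale >= 1):
            raise ConfigError(f"ri_scale must be an integer >= 1, got {self.ri_scale!r}")
        if not (math.isfinite(self.medium_ri) and self.medium_ri >= 1.0):
            raise ConfigError(f"medium_ri must be >= 1.0, got {self.medium_ri!r}")
        if not (0.0 < self.z_floor_fraction <= 1.0):
            raise ConfigError(
                f"z_floor_fraction must lie in (0, 1], got {self.z_floor_fraction!r}"
            )
        if self.connectivity_2d not in _VALID_CONN_2D:
            raise ConfigError(
                f"connectivity_2d must be one of {_VALID_CONN_2D}, got {self.connectivity_2d!r}"
            )
        if self.connectivity_3d not in _VALID_CONN_3D:
            raise ConfigError(
                f"connectivity_3d must be one of {_VALID_CONN_3D}, got {self.connectivity_3d!r}"
            )
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ConfigError(f"alpha must be > 0, got {self.alpha!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geom = d.pop("geometry", None)
        if geom is not None:
            if isinstance(geom, dict):
                geom = VoxelGeometry(**geom)
            d["geometry"] = geom
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a :class:`RunConfig` to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
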