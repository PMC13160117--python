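"""Simulation configuration: schema, validation, (de)serialization.

Configs are nested key-value documents (JSON or TOML; YAML if PyYAML is
importable) with five blocks -- tensor, geometry, orientation, dynamics,
acquisition, grid -- mirroring the simulation parameters.  Unknown keys are
rejected with their full path, and a config round-trips losslessly through
``to_dict``/``from_dict`` and the file writers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .tensors import InteractionTensor

__all__ = ["SimulationConfig", "ConfigError", "TensorConfig",
           "GeometryConfig", "DynamicsConfig", "AcquisitionConfig",
           "GridConfig"]

NUCLEI = ("P31", "N14", "H2")
ORIENTATIONS = ("parallel", "perpendicular")
GEOMETRY_KINDS = ("bicelle", "pore", "dimple")


class ConfigError(ValueError):
    """Schema violation, reported with the offending key path."""


@dataclass
class TensorConfig:
    """magnitude: delta_CSA in ppm (P31) or Cq in Hz (N14/H2)."""

    magnitude: float = 15000.0
    eta: float = 0.0
    iso: float = 0.0
    larmor_mhz: float | None = None


@dataclass
class GeometryConfig:
    kind: str = "bicelle"
    b_nm: float = 2.0
    d_nm: float = 1.8
    q: float = 2.0
    R_nm: float | None = None
    pore_a_nm: float = 2.0
    dimple_a_nm: float = 10.0
    dimple_depth_ratio: float = 0.0
    ring_counts: list | None = None


@dataclass
class DynamicsConfig:
    """Either a relative rate (qualitative mode) or D_ld in m^2/s with
    ``absolute_mode`` (rates in s^-1 via the real lipid spacings)."""

    relative_rate: float = 1.0
    d_ld_m2_per_s: float | None = None
    absolute_mode: bool = False
    t2_inv: float = 0.0

    def rate(self) -> float:
        if self.absolute_mode:
            if self.d_ld_m2_per_s is None:
                raise ConfigError("dynamics.d_ld_m2_per_s required in "
                                  "absolute mode")
            return self.d_ld_m2_per_s
        return self.relative_rate


@dataclass
class AcquisitionConfig:
    """dwell_us = 0/None selects an automatic spectral width of 4x the
    static edge frequency."""

    dwell_us: float | None = None
    n_points: int = 2048
    zero_fill: int = 4
    lb_hz: float = 50.0


@dataclass
class GridConfig:
    n_theta: int = 200
    n_phi: int = 8


@dataclass
class SimulationConfig:
    nucleus: str = "N14"
    orientation: str = "parallel"
    tensor: TensorConfig = field(default_factory=TensorConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    grid: GridConfig = field(default_factory=GridConfig)

    def __post_init__(self) -> None:
        if self.nucleus not in NUCLEI:
            raise ConfigError(f"nucleus: must be one of {NUCLEI}, "
                              f"got {self.nucleus!r}")
        if self.orientation not in ORIENTATIONS:
            raise ConfigError(f"orientation: must be one of {ORIENTATIONS}")
        if self.geometry.kind not in GEOMETRY_KINDS:
            raise ConfigError(
                f"geometry.kind: must be one of {GEOMETRY_KINDS}")
        if self.acquisition.n_points < 2:
            raise ConfigError("acquisition.n_points: must be >= 2")
        if self.acquisition.lb_hz < 0:
            raise ConfigError("acquisition.lb_hz: must be >= 0")
        if self.grid.n_theta < 2:
            raise ConfigError("grid.n_theta: must be >= 2")
        if self.grid.n_phi < 1:
            raise ConfigError("grid.n_phi: must be >= 1")

    # -- domain object helpers -------------------------------------------
    def tensor_object(self) -> InteractionTensor:
        t = self.tensor
        return InteractionTensor.for_nucleus(
            self.nucleus, t.magnitude, eta=t.eta, iso=t.iso,
            larmor_mhz=t.larmor_mhz)

    def orientation_mode(self) -> str:
        return ("n_parallel_B" if self.orientation == "parallel"
                else "n_perpendicular_B")

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        blocks = {"tensor": TensorConfig, "geometry": GeometryConfig,
                  "dynamics": DynamicsConfig,
                  "acquisition": AcquisitionConfig, "grid": GridConfig}
        kwargs = {}
        for key, value in data.items():
            if key in blocks:
                if not isinstance(value, dict):
                    raise ConfigError(f"{key}: expected a table/object")
                names = {f.name for f in dataclasses.fields(blocks[key])}
                for sub in value:
                    if sub not in names:
                        raise ConfigError(f"unknown key {key}.{sub}")
                kwargs[key] = blocks[key](**value)
            elif key in ("nucleus", "orientation"):
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown key {key}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        elif path.suffix in (".yml", ".yaml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            raise ConfigError(f"unsupported config format {path.suffix!r}")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix != ".json":
            raise ConfigError("config writing supports .json")
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
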