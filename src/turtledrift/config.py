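"""Run configuration: schema, YAML loading, validation and hashing.

A run is described by one YAML document with a forcing source (synthetic
generator parameters or netCDF paths), a species block overriding any of
the leatherback defaults, a release block, the simulation mode and
duration, a seed, and diagnostic options.  The configuration is validated
before any computation, and its SHA-256 hash is recorded in every output
so results can be traced back to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .params import ConfigError, SpeciesParams
from .synthetic import SyntheticForcingConfig

__all__ = ["ReleaseConfig", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class ReleaseConfig:
    """Release cohort: size, date window, truncated-normal peak, box."""

    n: int = 5000
    start: str = "2000-06-01"
    end: str = "2000-11-30"
    peak: str = "2000-09-15"
    sigma_days: float = 30.0
    box_center: tuple[float, float] = (137.0, 13.5)
    box_width: float = 0.25

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("release.n must be at least 1")
        if np.datetime64(self.end) < np.datetime64(self.start):
            raise ConfigError("empty release window")
        if self.sigma_days <= 0:
            raise ConfigError("release.sigma_days must be positive")


@dataclass(frozen=True)
class DiagnosticsConfig:
    meridian: float = -140.0
    density_bin: float = 1.0
    heading_bin: float = 10.0
    region: tuple[float, float, float, float] | None = None
    age_min: float = 3.0


@dataclass(frozen=True)
class RunConfig:
    """Validated settings of one simulation run."""

    forcing_netcdf: str | None = None
    forcing_names: dict = field(default_factory=dict)
    synthetic: SyntheticForcingConfig = field(default_factory=SyntheticForcingConfig)
    species: SpeciesParams = field(default_factory=SpeciesParams)
    release: ReleaseConfig = field(default_factory=ReleaseConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    mode: str = "active"
    years: float = 18.0
    seed: int = 0
    cold_threshold_days: int = 10
    cold_mode: str = "consecutive"
    coast_mode: str = "slip"
    age_bin_years: float = 0.1
    output_dir: str = "out"

    def __post_init__(self):
        if self.mode not in ("active", "passive"):
            raise ConfigError(f"mode must be 'active' or 'passive', got {self.mode!r}")
        if self.cold_mode not in ("consecutive", "cumulative"):
            raise ConfigError("cold.mode must be 'consecutive' or 'cumulative'")
        if self.coast_mode not in ("slip", "reflect"):
            raise ConfigError("coast_mode must be 'slip' or 'reflect'")
        if self.cold_threshold_days < 1:
            raise ConfigError("cold.threshold_days must be at least 1")
        if self.years < 1:
            raise ConfigError("years must be at least 1")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def _build(section: dict, cls):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    kwargs: dict = {}
    forcing = raw.pop("forcing", {})
    if "netcdf" in forcing:
        kwargs["forcing_netcdf"] = forcing["netcdf"].get("path")
        kwargs["forcing_names"] = forcing["netcdf"].get("names", {})
    if "synthetic" in forcing:
        kwargs["synthetic"] = _build(forcing["synthetic"], SyntheticForcingConfig)
    if "species" in raw:
        kwargs["species"] = _build(raw.pop("species"), SpeciesParams)
    if "release" in raw:
        rel = raw.pop("release")
        if "box_center" in rel:
            rel["box_center"] = tuple(rel["box_center"])
        kwargs["release"] = _build({k: str(v) if k in ("start", "end", "peak") else v
                                    for k, v in rel.items()}, ReleaseConfig)
    if "diagnostics" in raw:
        diag = raw.pop("diagnostics")
        if diag.get("region") is not None:
            diag["region"] = tuple(diag["region"])
        kwargs["diagnostics"] = _build(diag, DiagnosticsConfig)
    cold = raw.pop("cold", {})
    if "threshold_days" in cold:
        kwargs["cold_threshold_days"] = cold["threshold_days"]
    if "mode" in cold:
        kwargs["cold_mode"] = cold["mode"]
    if "output" in raw:
        kwargs["output_dir"] = raw.pop("output").get("directory", "out")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key, val in raw.items():
        if key not in known:
            raise ConfigError(f"unknown configuration key {key!r}")
        kwargs[key] = val
    return RunConfig(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    return obj


def config_hash(config: RunConfig) -> str:
    """Deterministic SHA-256 hex digest of the full configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
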