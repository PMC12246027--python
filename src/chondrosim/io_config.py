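"""Configuration loading with unit handling, result writers, run manifests.

A run configuration is a YAML/JSON document with nested blocks
(``material``, ``profile``, ``mesh``, ``load``, ``thresholds``,
``kinetics``, ``schedule``, ``zones``, ``output``).  Every dimensional
quantity may carry a unit tag ("0.2484 1/h", "2 mM", "0.9 MPa"); values are
normalized to SI at load time.  Unknown keys are rejected with the offending
key named.  Omitted blocks fall back to the "mature bovine reference"
preset - the single source of defaults, so parameter sweeps are config
overlays, not code branches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biokinetics import KineticsGrid, KineticsParams, TreatmentSchedule
from .cell_damage import DamageThresholds, ZoneSpec
from .constitutive import DepthProfile, MaterialParams
from .impact_solver import LoadSpec, MeshSpec
from .units import UnitError, to_si

__all__ = ["RunConfig", "ConfigError", "load_config", "config_hash",
           "write_results", "default_config"]


class ConfigError(ValueError):
    """Schema violation: unknown key, missing block, or bad unit."""


_INT_FIELDS = {"n_r", "n_z"}
_STR_FIELDS = {"name"}


def _build_block(cls, block: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, raw in block.items():
        if key not in valid:
            raise ConfigError(
                f"unknown key {key!r} in block {name!r}; expected one of {sorted(valid)}")
        if key in _STR_FIELDS or isinstance(raw, bool):
            kwargs[key] = raw
            continue
        if isinstance(raw, (list, tuple)):
            kwargs[key] = np.array([to_si(v) for v in raw])
            continue
        try:
            v = to_si(raw)
        except UnitError as exc:
            raise ConfigError(f"{name}.{key}: {exc}") from exc
        kwargs[key] = int(v) if key in _INT_FIELDS else v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid block {name!r}: {exc}") from exc


@dataclass
class RunConfig:
    """Validated, unit-normalized run configuration."""

    material: MaterialParams = field(default_factory=MaterialParams)
    profile: DepthProfile | None = None
    mesh: MeshSpec = field(default_factory=MeshSpec)
    load: LoadSpec = field(default_factory=LoadSpec)
    thresholds: DamageThresholds = field(default_factory=DamageThresholds)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)
    grid: KineticsGrid = field(default_factory=KineticsGrid)
    zones: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def digest(self) -> str:
        return config_hash(self.raw)


_BLOCK_TYPES = {
    "material": MaterialParams,
    "mesh": MeshSpec,
    "load": LoadSpec,
    "thresholds": DamageThresholds,
    "kinetics": KineticsParams,
    "schedule": TreatmentSchedule,
    "grid": KineticsGrid,
}


def default_config() -> RunConfig:
    """The mature-bovine reference preset (all defaults)."""
    from .fixtures import make_depth_profile_fixture

    return RunConfig(profile=make_depth_profile_fixture(), raw={})


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping of blocks")
    known = set(_BLOCK_TYPES) | {"profile", "zones", "output"}
    for key in doc:
        if key not in known:
            raise ConfigError(f"unknown config block {key!r}; expected one of {sorted(known)}")
    kwargs = {}
    for name, cls in _BLOCK_TYPES.items():
        if name in doc:
            if not isinstance(doc[name], dict):
                raise ConfigError(f"block {name!r} must be a mapping")
            kwargs[name] = _build_block(cls, doc[name], name)
    if "profile" in doc:
        kwargs["profile"] = _build_block(DepthProfile, doc["profile"], "profile")
    else:
        from .fixtures import make_depth_profile_fixture

        kwargs["profile"] = make_depth_profile_fixture()
    zones = {}
    for zname, zblock in (doc.get("zones") or {}).items():
        zones[zname] = _build_block(ZoneSpec, dict(zblock, name=zname), f"zones.{zname}")
    kwargs["zones"] = zones
    kwargs["output"] = doc.get("output") or {}
    return RunConfig(raw=doc, **kwargs)


def config_hash(doc: dict) -> str:
    """Stable hash of the raw configuration document."""
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(results, out_dir, config: RunConfig | None = None) -> list[Path]:
    """Write scenario tables as CSV plus a run manifest.

    ``results`` is a ScenarioResult, a DataFrame, or an iterable of either.
    Overwrites idempotently.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(results, (list, tuple)):
        results = [results]
    written = []
    manifest = {"config_hash": config.digest() if config is not None else None,
                "files": [], "package": "chondrosim"}
    try:
        from importlib.metadata import version

        manifest["version"] = version("chondrosim")
    except Exception:
        manifest["version"] = "unknown"
    for i, res in enumerate(results):
        if isinstance(res, pd.DataFrame):
            name, table, prov = f"table_{i}", res, {}
        else:
            name, table, prov = res.scenario, res.table, res.provenance
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
        manifest["files"].append({"name": name, "path": p.name, "provenance":
                                  {k: str(v) for k, v in prov.items()}})
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    written.append(mpath)
    return written
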