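"""Configuration parsing/validation and result serialization.

A run configuration is a YAML key tree mirroring :class:`SimulationConfig`;
every unset key falls back to the built-in defaults, unknown keys are
rejected, and a resolved configuration round-trips exactly through
write -> reload.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .driver import SimulationConfig, SimulationResult
from .geometry import GeometrySpec
from .healing import MechanoRegParams
from .remodelling import RemodelParams
from .vtkio import write_vtk

__all__ = ["RunManifest", "load_config", "dump_config", "write_outputs"]

_SUBCONFIGS = {
    "geometry": GeometrySpec,
    "healing": MechanoRegParams,
    "remodelling": RemodelParams,
}
_TUPLE_FIELDS = {"thresholds", "sn_constants", "surface_poly", "breakpoints"}


def _build(cls, data: dict, prefix: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(
            f"unknown configuration key(s) {sorted(unknown)} under '{prefix}'"
        )
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ValueError as err:
        raise ValueError(f"invalid configuration under '{prefix}': {err}") from err


def load_config(source) -> SimulationConfig:
    """Load and validate a simulation configuration.

    ``source`` may be a path to a YAML file or an already-parsed mapping;
    an empty configuration resolves to all built-in defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")

    top_names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise KeyError(f"unknown configuration key(s) {sorted(unknown)}")

    kwargs = {}
    for key, value in data.items():
        if key in _SUBCONFIGS:
            if isinstance(value, dict):
                value = _build(_SUBCONFIGS[key], value, key)
            kwargs[key] = value
        else:
            kwargs[key] = value
    try:
        return SimulationConfig(**kwargs)
    except ValueError as err:
        raise ValueError(f"invalid configuration: {err}") from err


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    parameters: dict
    version: str
    n_increments: int
    union_day: float | None
    transition_day: float | None
    status: str
    wall_time_s: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_outputs(result: SimulationResult, out_dir,
                  mesh=None, wall_time_s: float = 0.0) -> RunManifest:
    """Serialize a finished run: CSV time series, dt log, snapshot, manifest.

    Identical configurations produce byte-identical CSV output (all default
    algorithms are deterministic).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result.series.to_csv(out / "series.csv", index=False, float_format="%.10g")
    with open(out / "dt_log.csv", "w") as fh:
        fh.write("t,dt\n")
        for t, dt in result.dt_log:
            fh.write(f"{t:.10g},{dt:.10g}\n")

    manifest = RunManifest(
        config_hash=config_hash(result.config),
        parameters=result.config.to_dict(),
        version=__version__,
        n_increments=len(result.dt_log),
        union_day=result.union_day,
        transition_day=result.transition_day,
        status=result.status,
        wall_time_s=wall_time_s,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)

    if mesh is not None:
        cell_data = {"region": result.snapshot["region"]}
        for key, arr in result.snapshot.items():
            if key != "region":
                cell_data[key] = arr
        write_vtk(out / "final_state.vtk", mesh, cell_data=cell_data)
    return manifest
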