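"""Configuration parsing, NetCDF/CSV output and provenance manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import xarray as xr
import yaml

from . import __version__
from .experiments import ExperimentConfig, RunResult, WarmingRamp, build_config
from .params import EcosystemParams
from .state import LAYERS, TRACER_UNITS, TRACERS

_PARAM_FIELDS = {f.name for f in dataclasses.fields(EcosystemParams)}
_RAMP_FIELDS = {f.name for f in dataclasses.fields(WarmingRamp)}
_CONFIG_FIELDS = {"paradigm", "scenario", "denitrification_enabled",
                  "steps_per_year", "spinup_tol_per_century",
                  "spinup_max_years", "spinup_check_years", "seed"}


def load_config(path) -> Tuple[ExperimentConfig, EcosystemParams]:
    """Parse a flat YAML config file into validated objects.

    Every :class:`EcosystemParams` field is addressable by name; ramp fields
    use a ``ramp_`` prefix.  Unknown keys are rejected and paradigm
    constraints are enforced at load time.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    paradigm = raw.pop("paradigm", "CONTR")
    overrides, config_kwargs, ramp_kwargs, unknown = {}, {}, {}, []
    for key, value in raw.items():
        if key in _PARAM_FIELDS:
            overrides[key] = value
        elif key in _CONFIG_FIELDS:
            config_kwargs[key] = value
        elif key.startswith("ramp_") and key[5:] in _RAMP_FIELDS:
            ramp_kwargs[key[5:]] = value
        else:
            unknown.append(key)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if ramp_kwargs:
        config_kwargs["ramp"] = WarmingRamp(**ramp_kwargs)
    config = build_config(paradigm, overrides, **config_kwargs)
    return config, config.params


def dump_config(config: ExperimentConfig, path) -> None:
    """Write a config back to the flat YAML dialect of :func:`load_config`."""
    flat = {"paradigm": config.paradigm}
    for key in sorted(_CONFIG_FIELDS - {"paradigm"}):
        flat[key] = getattr(config, key)
    for key in sorted(_RAMP_FIELDS):
        flat[f"ramp_{key}"] = getattr(config.ramp, key)
    for key in sorted(_PARAM_FIELDS):
        flat[key] = getattr(config.params, key)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trajectory / diagnostics output
# ---------------------------------------------------------------------------

def trajectory_to_dataset(run: RunResult) -> xr.Dataset:
    """Annual-mean trajectory as a self-describing dataset."""
    res, geom = run.result, run.geometry
    coords = {"time": ("time", res.years, {"units": "year"}),
              "box": ("box", list(geom.names)),
              "layer": ("layer", list(LAYERS))}
    data = {}
    for k, name in enumerate(TRACERS):
        data[name] = (("time", "box", "layer"),
                      res.traj[:, :, :, k].transpose(0, 1, 2),
                      {"units": TRACER_UNITS[name]})
    data["fixation"] = (("time", "box"), res.fixation,
                        {"units": "mmol N m-3 d-1"})
    data["denitrification"] = (("time", "box"), res.denit,
                               {"units": "mmol N m-3 d-1"})
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["config_hash"] = run.config.config_hash
    ds.attrs["paradigm"] = run.config.paradigm
    return ds


def read_trajectory(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    ds.load()
    ds.close()
    return ds


@dataclass
class RunManifest:
    """Provenance record: config hash, versions, seeds, file digests."""

    config_hash: str
    package_version: str
    seed: int
    solver: dict
    files: dict               # filename -> sha256
    wall_clock: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(run: RunResult, outdir) -> RunManifest:
    """Write NetCDF trajectory, CSV diagnostics and a provenance manifest.

    Partial outputs are removed if any write fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj_path = outdir / "trajectory.nc"
    diag_path = outdir / "diagnostics.csv"
    written = []
    try:
        trajectory_to_dataset(run).to_netcdf(traj_path, engine="scipy")
        written.append(traj_path)
        run.diagnostics.to_frame().to_csv(diag_path, index=False)
        written.append(diag_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    manifest = RunManifest(
        config_hash=run.config.config_hash,
        package_version=__version__,
        seed=run.config.seed,
        solver={"scheme": "rk4", "steps_per_year": run.config.steps_per_year},
        files={p.name: _sha256(p) for p in written},
        wall_clock=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
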