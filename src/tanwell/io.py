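"""Config parsing, run manifests, and CSV serialization.

Plain-text formats throughout: YAML for configuration, long-format CSV
for field profiles, wide CSV for observable series, JSON for the run
manifest.  A manifest records everything needed to reproduce a run bit
for bit (the model is deterministic): resolved parameters, geometry,
grid spacing, solver configuration and the scenario definition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import ConfigurationError, Geometry, build_grid
from .kinetics import FIELDS, TreatmentFlags
from .parameters import (
    ParameterSet,
    default_dimensionless_parameters,
    scenario_overrides,
)
from .scenarios import (
    DEFAULT_T_END,
    Scenario,
    make_scenario,
    observable_series,
    run_scenario,
)
from .solver import SolverConfig, Trajectory

__all__ = [
    "load_config",
    "write_outputs",
    "read_profiles",
    "read_observables",
    "build_manifest",
    "replay_manifest",
]

_TOP_KEYS = {"scenario", "geometry", "solver", "parameters"}
_SCENARIO_KEYS = {"name", "t_end", "output_times", "overrides", "n0", "N1_0",
                  "rho0", "lam_A", "tgfb_level", "tgfb_mode"}
_GEOMETRY_KEYS = {"x_min", "x_max", "x_membrane", "ecm_interval",
                  "injection_interval", "h"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section {where!r}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path) -> tuple[ParameterSet, Geometry, SolverConfig, Scenario]:
    """Parse and validate a YAML run configuration.

    An empty file yields all defaults (table-derived dimensionless
    parameters, default transwell geometry, the ``control`` scenario).
    The grid spacing may be given as ``geometry.h`` (default 0.01) and is
    carried on the returned geometry object as an attribute ``h``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<root>")

    geo_sec = dict(raw.get("geometry") or {})
    _check_keys(geo_sec, _GEOMETRY_KEYS, "geometry")
    h = float(geo_sec.pop("h", 0.01))
    for k in ("ecm_interval", "injection_interval"):
        if k in geo_sec and geo_sec[k] is not None:
            geo_sec[k] = tuple(float(v) for v in geo_sec[k])
    geometry = Geometry(**geo_sec)
    build_grid(geometry, h)  # validate divisibility early
    object.__setattr__(geometry, "h", h)

    params = default_dimensionless_parameters()
    params = scenario_overrides(params, dict(raw.get("parameters") or {}))

    sol_sec = dict(raw.get("solver") or {})
    allowed = {f.name for f in dataclasses.fields(SolverConfig)}
    _check_keys(sol_sec, allowed, "solver")
    solver_cfg = SolverConfig(**sol_sec)

    sc_sec = dict(raw.get("scenario") or {})
    _check_keys(sc_sec, _SCENARIO_KEYS, "scenario")
    name = sc_sec.pop("name", "control")
    sc_sec.setdefault("t_end", DEFAULT_T_END)
    scenario = make_scenario(name, geometry=geometry, **sc_sec)
    return params, geometry, solver_cfg, scenario


# ---------------------------------------------------------------------------
# outputs


def _profiles_frame(traj: Trajectory, grid) -> pd.DataFrame:
    recs = []
    x = grid.cell_centers
    for state in traj.states:
        for name in FIELDS:
            vals = state[name]
            recs.append(pd.DataFrame(
                {"t": state.t, "x": x, "variable": name, "value": vals}
            ))
    return pd.concat(recs, ignore_index=True)


def _params_hash(p: ParameterSet) -> str:
    blob = json.dumps(p.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_manifest(
    scenario: Scenario,
    params: ParameterSet,
    geometry: Geometry,
    solver_cfg: SolverConfig,
    traj: Trajectory,
    h: float,
    wall_start: float,
    wall_end: float,
) -> dict:
    resolved = scenario.resolve_parameters(params)
    return {
        "tanwell_version": __version__,
        "scenario": dataclasses.asdict(scenario),
        "parameters": resolved.to_dict(),
        "parameter_hash": _params_hash(resolved),
        "geometry": dataclasses.asdict(geometry),
        "grid_h": h,
        "solver": dataclasses.asdict(solver_cfg),
        "wall_time_start": wall_start,
        "wall_time_end": wall_end,
        "solver_stats": traj.stats,
    }


def write_outputs(
    traj: Trajectory,
    observables: pd.DataFrame,
    manifest: dict,
    out_dir,
    grid,
) -> dict[str, Path]:
    """Write profiles CSV, observables CSV and the JSON manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "profiles": out / "profiles.csv",
            "observables": out / "observables.csv",
            "manifest": out / "manifest.json",
        }
        _profiles_frame(traj, grid).to_csv(files["profiles"], index=False)
        observables.to_csv(files["observables"], index=False)
        files["manifest"].write_text(json.dumps(manifest, indent=2, default=float))
    except OSError as exc:
        raise ConfigurationError(f"cannot write outputs under {out}: {exc}") from exc
    return files


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_observables(path) -> pd.DataFrame:
    return pd.read_csv(path)


def replay_manifest(path) -> tuple[Trajectory, pd.DataFrame]:
    """Re-run a simulation from its manifest (bit-reproducible)."""
    man = json.loads(Path(path).read_text())
    geo_kwargs = dict(man["geometry"])
    for k in ("ecm_interval", "injection_interval"):
        if geo_kwargs.get(k) is not None:
            geo_kwargs[k] = tuple(geo_kwargs[k])
    geometry = Geometry(**geo_kwargs)
    sc = dict(man["scenario"])
    sc["flags"] = TreatmentFlags(**sc["flags"])
    sc["initial"] = {
        name: [(tuple(interval), mag) for interval, mag in pieces]
        for name, pieces in sc["initial"].items()
    }
    sc["output_times"] = tuple(sc["output_times"])
    scenario = Scenario(**sc)
    params = ParameterSet(**man["parameters"])
    solver_cfg = SolverConfig(**man["solver"])
    h = man["grid_h"]
    traj = run_scenario(scenario, p=params, geometry=geometry, h=h, cfg=solver_cfg)
    grid = build_grid(geometry, h)
    return traj, observable_series(traj, grid)
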