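"""Configuration files, result serialization, and test-fixture generation.

Configurations are YAML with nested sections ``plus_motor``, ``minus_motor``,
``tips``, ``scenario``, ``solver`` and an optional free-form ``meta``
section.  All quantities are in base units (µm, s, µm²/s); keys are the
field names of the corresponding dataclasses.  Unspecified keys fall back to
the baseline defaults; unknown keys are an error, never silently ignored.

Outputs are plain delimited text (full double precision) plus a JSON run
record that echoes every resolved parameter, so a run can be reproduced
bit-identically from its own output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .params import (
    ModelParams,
    ScenarioConfig,
    table1_defaults,
    validate_params,
)
from .scenarios import BUILTIN_SCENARIOS, builtin_scenario
from .solver import FullFieldState, SolverConfig, Trajectory

__all__ = [
    "RunRecord",
    "read_config",
    "config_to_dict",
    "write_outputs",
    "read_trajectory",
    "generate_fixtures",
]

logger = logging.getLogger("mtends")

_MOTOR_KEYS = ("v", "D_on", "D_off", "k_on", "k_off", "direction")
_TIP_KEYS = (
    "alpha_plus", "alpha_minus", "beta_plus",
    "beta_minus", "gamma_plus", "gamma_minus",
)
_SCENARIO_KEYS = ("name", "L0", "t_end", "initial_density_spec")
_SOLVER_KEYS = (
    "n_cells", "rel_tol", "abs_tol", "L_min", "L_max", "save_every",
    "ic_mode", "freeze_tips", "method", "advection_scheme",
)


@dataclasses.dataclass(frozen=True)
class RunRecord:
    """Provenance record written next to every set of outputs."""

    config: dict
    version: str
    wall_time_s: float
    termination: str
    outputs: tuple


def _check_keys(section: dict, allowed, path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigurationError(
                f"unknown key {path}.{key!r}; allowed: {sorted(allowed)}"
            )


def _merge(defaults, section: dict, allowed, path: str):
    _check_keys(section, allowed, path)
    return dataclasses.replace(defaults, **section)


def read_config(path) -> tuple[ScenarioConfig, SolverConfig]:
    """Read a scenario + solver configuration from a YAML file.

    An empty file resolves to the baseline defaults (L0 = 10 µm,
    t_end = 300 s).  Raises :class:`ConfigurationError` naming the offending
    key path on unknown keys or parse failure.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    _check_keys(
        raw,
        ("plus_motor", "minus_motor", "tips", "scenario", "solver", "meta"),
        "config",
    )
    defaults = table1_defaults()
    plus = _merge(defaults.plus_motor, raw.get("plus_motor", {}),
                  _MOTOR_KEYS, "plus_motor")
    minus = _merge(defaults.minus_motor, raw.get("minus_motor", {}),
                   _MOTOR_KEYS, "minus_motor")
    tips = _merge(defaults.tips, raw.get("tips", {}), _TIP_KEYS, "tips")
    params = ModelParams(plus_motor=plus, minus_motor=minus, tips=tips)
    validate_params(params)

    scen_raw = dict(raw.get("scenario", {}))
    _check_keys(scen_raw, _SCENARIO_KEYS, "scenario")
    scen_raw.setdefault("name", path.stem)
    scenario = ScenarioConfig(params=params, **scen_raw)
    scenario.validate()

    solver = _merge(SolverConfig(), raw.get("solver", {}), _SOLVER_KEYS, "solver")
    solver.validate(scenario.L0)
    return scenario, solver


def config_to_dict(scenario: ScenarioConfig, solver: SolverConfig) -> dict:
    """Echo every resolved parameter as a plain nested dict (YAML/JSON safe)."""
    return {
        "plus_motor": dataclasses.asdict(scenario.params.plus_motor),
        "minus_motor": dataclasses.asdict(scenario.params.minus_motor),
        "tips": dataclasses.asdict(scenario.params.tips),
        "scenario": {
            "name": scenario.name,
            "L0": scenario.L0,
            "t_end": scenario.t_end,
            "initial_density_spec": scenario.initial_density_spec,
        },
        "solver": {
            k: getattr(solver, k) for k in _SOLVER_KEYS
        },
    }


def write_outputs(
    traj: Trajectory,
    out_dir,
    scenario: ScenarioConfig | None = None,
    solver: SolverConfig | None = None,
    wall_time_s: float = float("nan"),
) -> RunRecord:
    """Write trajectory (and snapshot) tables plus a JSON run record.

    ``trajectory.tsv`` has columns ``t, L_minus, L_plus, length, dLplus_dt,
    dLminus_dt, termination``; ``snapshots.tsv`` (when the trajectory
    carries snapshots) has ``t, xi, x`` plus one column per field.  Numbers
    are serialized with the shortest exact (round-trip) representation, so a
    read-back reproduces the series bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []

    df = pd.DataFrame(
        {
            "t": traj.times,
            "L_minus": traj.L_minus_series,
            "L_plus": traj.L_plus_series,
            "length": traj.length_series,
            "dLplus_dt": traj.tip_velocity_series[:, 0],
            "dLminus_dt": traj.tip_velocity_series[:, 1],
            "termination": traj.termination,
        }
    )
    traj_path = out_dir / "trajectory.tsv"
    df.to_csv(traj_path, sep="\t", index=False)
    outputs.append(str(traj_path))

    if traj.snapshots:
        frames = []
        for snap in traj.snapshots:
            cols = {"t": snap.t, "xi": snap.xi, "x": snap.x}
            if isinstance(snap, FullFieldState):
                cols.update(p=snap.p, c=snap.c, m=snap.m, f=snap.f)
            else:
                cols.update(q=snap.q, h=snap.h)
            frames.append(pd.DataFrame(cols))
        snap_path = out_dir / "snapshots.tsv"
        pd.concat(frames, ignore_index=True).to_csv(snap_path, sep="\t", index=False)
        outputs.append(str(snap_path))

    config = (
        config_to_dict(scenario, solver or SolverConfig())
        if scenario is not None
        else {}
    )
    record = RunRecord(
        config=config,
        version=__version__,
        wall_time_s=wall_time_s,
        termination=traj.termination,
        outputs=tuple(outputs),
    )
    record_path = out_dir / "run_record.json"
    record_path.write_text(json.dumps(dataclasses.asdict(record), indent=2))
    logger.info("wrote %d output files to %s", len(outputs) + 1, out_dir)
    return record


def read_trajectory(path) -> Trajectory:
    """Read a trajectory table written by :func:`write_outputs`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return Trajectory(
        times=df["t"].to_numpy(),
        L_minus_series=df["L_minus"].to_numpy(),
        L_plus_series=df["L_plus"].to_numpy(),
        length_series=df["length"].to_numpy(),
        tip_velocity_series=df[["dLplus_dt", "dLminus_dt"]].to_numpy(),
        termination=str(df["termination"].iloc[0]),
        snapshots=[],
    )


def _scenario_yaml(sc: ScenarioConfig, meta: dict | None = None) -> str:
    doc = config_to_dict(sc, SolverConfig())
    del doc["solver"]  # fixtures carry model + scenario, solver stays default
    if meta:
        doc["meta"] = meta
    return yaml.safe_dump(doc, sort_keys=False)


def generate_fixtures(out_dir, n_random: int = 0, seed: int = 0) -> list[str]:
    """Write the four built-in scenario configs plus ``n_random`` random but
    valid parameter sets.

    Random sets draw every positive baseline rate log-uniformly within one
    decade either side of its default (a parameter whose default is zero
    stays zero), and are tagged in their ``meta`` section with whether the
    adiabatic equilibrium-existence condition α₊+α₋ > γ₊+γ₋ holds.
    Deterministic for a fixed seed.
    """
    if n_random < 0:
        raise ConfigurationError("n_random must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in BUILTIN_SCENARIOS:
        sc = builtin_scenario(name)
        p = out_dir / f"{name}.yaml"
        p.write_text(_scenario_yaml(sc))
        written.append(str(p))

    rng = np.random.default_rng(seed)
    base = table1_defaults()

    def jitter(x: float) -> float:
        if x == 0.0:
            return 0.0
        return float(x * 10.0 ** rng.uniform(-1.0, 1.0))

    for i in range(n_random):
        plus = dataclasses.replace(
            base.plus_motor,
            **{k: jitter(getattr(base.plus_motor, k))
               for k in ("v", "D_on", "D_off", "k_on", "k_off")},
        )
        minus = dataclasses.replace(
            base.minus_motor,
            **{k: jitter(getattr(base.minus_motor, k))
               for k in ("v", "D_on", "D_off", "k_on", "k_off")},
        )
        tips = dataclasses.replace(
            base.tips,
            **{k: jitter(getattr(base.tips, k)) for k in _TIP_KEYS},
        )
        params = ModelParams(plus_motor=plus, minus_motor=minus, tips=tips)
        exists = (
            tips.alpha_plus + tips.alpha_minus
            > tips.gamma_plus + tips.gamma_minus
        )
        sc = ScenarioConfig(name=f"random-{i:03d}", params=params,
                            L0=10.0, t_end=300.0)
        p = out_dir / f"random-{i:03d}.yaml"
        p.write_text(_scenario_yaml(sc, meta={"equilibrium_exists": bool(exists)}))
        written.append(str(p))
    return written
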