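"""Config parsing/validation and CSV/JSON readers and writers.

Formats are deliberately boring: JSON for configs and reports, CSV for
trajectories, every artifact versioned with ``schema_version`` and, for
stochastic outputs, stamped with the seed and a hash of the generating
configuration.  Validation errors always name the offending field with a
dotted path (``noise.sigma``), and unknown keys are rejected rather than
ignored so that typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .model import (
    EDAError,
    InitialConditions,
    RateConstants,
    Trajectory,
    MODES,
    PAPER_LITERAL,
)
from .sde import MarkLaw, NoiseSpec, SimOptions

__all__ = [
    "SCHEMA_VERSION",
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "write_config",
    "config_hash",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_report_json",
]

SCHEMA_VERSION = 1

REDUCED_COLUMNS = ["t", "x", "y", "n_jumps", "clamped"]
FULL_COLUMNS = ["t", "x", "y", "a", "b", "c", "d", "e", "n_jumps", "clamped"]


class ConfigError(EDAError):
    """A configuration file is malformed; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    """The union of all module configurations for one run."""

    rates: RateConstants
    init: InitialConditions
    noise: NoiseSpec
    sim: SimOptions
    mode: str = PAPER_LITERAL


def _require_keys(d: Dict, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where or 'top level'}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"missing required key(s) {sorted(missing)} in {where or 'top level'}")


def _num(d: Dict, key: str, where: str, default=None):
    if key not in d:
        return default
    v = d[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"{where}.{key} must be a number, got {v!r}")
    return float(v)


def config_from_dict(data: Dict) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a plain dict.

    Fills documented defaults (``sim.dt = 1e-3``, ``sim.t_end = 100``,
    ``mode = "paper_literal"``, zero noise) and rejects unknown keys.  All
    validation failures raise :class:`ConfigError` with a dotted field path.
    """
    _require_keys(
        data,
        {"schema_version", "rates", "init", "noise", "sim", "mode"},
        {"rates", "init"},
        "",
    )
    try:
        r = data["rates"]
        _require_keys(r, {"k1", "k_minus1", "k2"}, {"k1", "k_minus1", "k2"}, "rates")
        rates = RateConstants(
            k1=_num(r, "k1", "rates"),
            k_minus1=_num(r, "k_minus1", "rates"),
            k2=_num(r, "k2", "rates"),
        )
    except EDAError as exc:
        raise ConfigError(str(exc)) from exc
    try:
        i = data["init"]
        _require_keys(
            i, {"x0", "a0", "c0", "x_start", "y_start"}, {"x0", "a0", "c0"}, "init"
        )
        init = InitialConditions(
            x0=_num(i, "x0", "init"),
            a0=_num(i, "a0", "init"),
            c0=_num(i, "c0", "init"),
            x_start=_num(i, "x_start", "init", default=None),
            y_start=_num(i, "y_start", "init", default=0.0),
        )
    except EDAError as exc:
        raise ConfigError(str(exc)) from exc
    nz = data.get("noise", {})
    _require_keys(
        nz, {"sigma", "lambda_Y", "delta", "mark", "gamma_bound"}, set(), "noise"
    )
    mark_d = nz.get("mark", {"type": "constant", "gamma": 0.0})
    _require_keys(mark_d, {"type", "gamma", "low", "high"}, {"type"}, "noise.mark")
    try:
        mark = MarkLaw(
            type=mark_d["type"],
            gamma=_num(mark_d, "gamma", "noise.mark", default=0.0),
            low=_num(mark_d, "low", "noise.mark", default=0.0),
            high=_num(mark_d, "high", "noise.mark", default=0.0),
        )
        noise = NoiseSpec(
            sigma=_num(nz, "sigma", "noise", default=0.0),
            lambda_Y=_num(nz, "lambda_Y", "noise", default=0.0),
            mark=mark,
            delta=_num(nz, "delta", "noise", default=0.0),
            gamma_bound=_num(nz, "gamma_bound", "noise", default=None),
        )
    except EDAError as exc:
        raise ConfigError(str(exc)) from exc
    s = data.get("sim", {})
    _require_keys(s, {"dt", "t_end", "clamp", "record_full", "seed"}, set(), "sim")
    seed = s.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise ConfigError(f"sim.seed must be an integer or null, got {seed!r}")
    record_full = s.get("record_full", False)
    if not isinstance(record_full, bool):
        raise ConfigError(f"sim.record_full must be a boolean, got {record_full!r}")
    try:
        sim = SimOptions(
            dt=_num(s, "dt", "sim", default=1e-3),
            t_end=_num(s, "t_end", "sim", default=100.0),
            clamp=s.get("clamp", "clamp_zero"),
            record_full=record_full,
            seed=seed,
        )
    except EDAError as exc:
        raise ConfigError(str(exc)) from exc
    mode = data.get("mode", PAPER_LITERAL)
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    return RunConfig(rates=rates, init=init, noise=noise, sim=sim, mode=mode)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid JSON: {exc}")
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a JSON object")
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> Dict:
    """Serialise a config to the JSON schema (round-trips through
    :func:`config_from_dict`)."""
    mark = config.noise.mark
    mark_d: Dict = {"type": mark.type}
    if mark.type == "constant":
        mark_d["gamma"] = mark.gamma
    else:
        mark_d["low"] = mark.low
        mark_d["high"] = mark.high
    return {
        "schema_version": SCHEMA_VERSION,
        "rates": {
            "k1": config.rates.k1,
            "k_minus1": config.rates.k_minus1,
            "k2": config.rates.k2,
        },
        "init": {
            "x0": config.init.x0,
            "a0": config.init.a0,
            "c0": config.init.c0,
            "x_start": config.init.x_start,
            "y_start": config.init.y_start,
        },
        "noise": {
            "sigma": config.noise.sigma,
            "lambda_Y": config.noise.lambda_Y,
            "delta": config.noise.delta,
            "mark": mark_d,
        },
        "sim": {
            "dt": config.sim.dt,
            "t_end": config.sim.t_end,
            "clamp": config.sim.clamp,
            "record_full": config.sim.record_full,
            "seed": config.sim.seed,
        },
        "mode": config.mode,
    }


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2) + "\n")


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the configuration (for artifact provenance)."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------


def write_trajectory_csv(
    traj: Trajectory,
    path: str | Path,
    include_full: bool = False,
    init: InitialConditions | None = None,
    config_digest: str | None = None,
) -> None:
    """Write a trajectory as CSV (columns ``t,x,y[,a,b,c,d,e],n_jumps,clamped``).

    ``include_full`` lifts a reduced trajectory through the conservation
    laws (requires ``init``); inadmissible points raise with the row index.
    A leading ``#`` comment line embeds the schema version, seed and
    (optionally) the config hash.  Floats use shortest round-trip
    representation, so reading the file back reproduces them exactly.
    """
    if include_full and not traj.is_full:
        if init is None:
            raise ValueError("include_full requires init for reconstruction")
        traj = traj.with_full(init)
    per_row_jumps = np.concatenate([[0], traj.jump_counts])
    per_row_clamped = np.concatenate([[False], traj.clamp_flags]).astype(int)
    cols: Dict[str, np.ndarray] = {"t": traj.times}
    if traj.is_full:
        s = traj.states
        for j, name in enumerate(("x", "a", "y", "b", "c", "d", "e")):
            cols[name] = s[:, j]
        order = FULL_COLUMNS
    else:
        cols["x"] = traj.states[:, 0]
        cols["y"] = traj.states[:, 1]
        order = REDUCED_COLUMNS
    cols["n_jumps"] = per_row_jumps
    cols["clamped"] = per_row_clamped
    df = pd.DataFrame({k: cols[k] for k in order})
    header = (
        f"# schema_version={SCHEMA_VERSION} seed={traj.seed}"
        + (f" config={config_digest}" if config_digest else "")
        + "\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory_csv`."""
    path = Path(path)
    seed = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("seed="):
                    raw = token[len("seed="):]
                    seed = None if raw == "None" else int(raw)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    have = list(df.columns)
    if have == FULL_COLUMNS:
        states = df[["x", "a", "y", "b", "c", "d", "e"]].to_numpy()
    elif have == REDUCED_COLUMNS:
        states = df[["x", "y"]].to_numpy()
    else:
        raise ConfigError(
            f"{path}: unexpected trajectory schema {have}; expected "
            f"{REDUCED_COLUMNS} or {FULL_COLUMNS}"
        )
    return Trajectory(
        times=df["t"].to_numpy(),
        states=states,
        jump_counts=df["n_jumps"].to_numpy()[1:],
        clamp_flags=df["clamped"].to_numpy()[1:].astype(bool),
        seed=seed,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return repr(obj)  # JSON has no NaN/inf; keep them readable
    return obj


def write_report_json(report: Dict, path: str | Path) -> None:
    """Write a report dict as versioned JSON (floats at full precision)."""
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(report)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
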