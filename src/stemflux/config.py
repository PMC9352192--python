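"""YAML/JSON configuration parsing and serialization.

A config file describes a complete run: the pharmacodynamic parameter set
(one block per dose-dependent rate, using the model's symbol names), the
initial tumor state, the dose grid, the horizon, and optional cohort/sweep
blocks.  Parsing and re-serialization round-trip exactly.

Example::

    pharmacodynamics:
      b_S: 0.2
      b_R: 0.1
      k_RS: 0.01
      d_S:  {delta: 0.05, E: 0.3,  r: 0.3, P: 20.0}
      d_R:  {delta: 0.05, E: 0.03, r: 0.3, P: 20.0}
      k_SR: {delta: 0.01, E: 0.2,  r: 0.3, P: 50.0}
    initial_state: {N0: 1.0e9, resistant_fraction: 0.01}
    horizon: 2500.0
    doses: {start: 0.0, stop: 100.0, num: 101}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import TumorState, ValidationError
from .pharmacodynamics import LogisticResponse, PharmacodynamicSet

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "parse_pharmacodynamics",
    "parse_initial_state",
    "pharmacodynamics_to_config",
    "initial_state_to_config",
    "resolve_grid",
]


class ConfigError(ValueError):
    """Malformed or incomplete configuration."""


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    return data


def dump_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _require(block: dict, key: str, context: str):
    if key not in block:
        raise ConfigError(f"missing key {key!r} in {context}")
    return block[key]


def _parse_curve(block: dict, name: str) -> LogisticResponse:
    if not isinstance(block, dict):
        raise ConfigError(f"curve block {name!r} must be a mapping")
    try:
        return LogisticResponse(
            delta=float(_require(block, "delta", name)),
            E=float(_require(block, "E", name)),
            r=float(_require(block, "r", name)),
            P=float(_require(block, "P", name)),
        )
    except ValidationError as exc:
        raise ConfigError(f"invalid curve {name!r}: {exc}") from exc


def parse_pharmacodynamics(cfg: dict) -> PharmacodynamicSet:
    block = _require(cfg, "pharmacodynamics", "config")
    try:
        return PharmacodynamicSet(
            ds_curve=_parse_curve(_require(block, "d_S", "pharmacodynamics"), "d_S"),
            dr_curve=_parse_curve(_require(block, "d_R", "pharmacodynamics"), "d_R"),
            ksr_curve=_parse_curve(_require(block, "k_SR", "pharmacodynamics"), "k_SR"),
            b_S=float(_require(block, "b_S", "pharmacodynamics")),
            b_R=float(_require(block, "b_R", "pharmacodynamics")),
            k_RS=float(_require(block, "k_RS", "pharmacodynamics")),
        )
    except ValidationError as exc:
        raise ConfigError(f"invalid pharmacodynamics: {exc}") from exc


def parse_initial_state(cfg: dict) -> TumorState:
    block = _require(cfg, "initial_state", "config")
    N0 = float(_require(block, "N0", "initial_state"))
    f = float(_require(block, "resistant_fraction", "initial_state"))
    if N0 <= 0:
        raise ConfigError("initial_state.N0 must be positive")
    if not 0 <= f < 1:
        raise ConfigError("initial_state.resistant_fraction must lie in [0, 1)")
    return TumorState(x1=N0 * (1.0 - f), x2=N0 * f, t=0.0)


def pharmacodynamics_to_config(pd_set: PharmacodynamicSet) -> dict:
    """Inverse of :func:`parse_pharmacodynamics` (exact round-trip)."""
    return {"pharmacodynamics": pd_set.to_dict()}


def initial_state_to_config(x0: TumorState) -> dict:
    N0 = x0.N
    return {
        "initial_state": {"N0": N0, "resistant_fraction": x0.x2 / N0}
    }


def resolve_grid(spec, context: str = "grid") -> np.ndarray:
    """Turn a grid spec — explicit list or {start, stop, num} — into an array."""
    if isinstance(spec, dict):
        try:
            return np.linspace(
                float(spec["start"]), float(spec["stop"]), int(spec["num"])
            )
        except KeyError as exc:
            raise ConfigError(
                f"{context} mapping needs start/stop/num, got {sorted(spec)}"
            ) from exc
    arr = np.asarray(spec, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ConfigError(f"{context} must be a non-empty 1-D list")
    return arr


def write_manifest(path: str | Path, payload: dict) -> None:
    """Write a JSON provenance manifest capturing every resolved parameter."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default, sort_keys=True)
        fh.write("\n")
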