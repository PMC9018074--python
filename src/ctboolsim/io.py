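"""Configuration loading, run manifests and tidy-output helpers."""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from typing import Any

import yaml

from . import __version__
from .model import BooleanNetwork, parse_boolnet, parse_maboss, serialise_boolnet
from .perturb import DEFAULT_LEVELS
from .simulate import SimulationConfig

__all__ = [
    "load_config",
    "load_config_defaults",
    "load_model",
    "simulation_config_from",
    "write_manifest",
    "model_hash",
    "config_hash",
]

# key -> (type, default, validator)
_SCHEMA: dict[str, tuple] = {
    "n_trajectories": (int, 5000, lambda v: v > 0),
    "max_time": ((int, float), 20.0, lambda v: v > 0),
    "time_tick": ((int, float), 1.0, lambda v: v > 0),
    "seed": (int, 0, lambda v: True),
    "initial": (dict, {}, lambda v: all(0.0 <= p <= 1.0 for p in v.values())),
    "tracked": (list, None, lambda v: all(isinstance(n, str) for n in v)),
    "levels": (list, list(DEFAULT_LEVELS), lambda v: all(0.0 <= x <= 1.0 for x in v)),
    "mode": (str, "mixture_ko_wt", lambda v: v in ("mixture_ko_wt", "frozen_on_off")),
    "preset": (str, None, lambda v: True),
    "recipe": (dict, {}, lambda v: True),
}


def load_config(path: str) -> dict[str, Any]:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected (with their key path); missing keys are
    filled with defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    config: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        expected, _, validator = _SCHEMA[key]
        if not isinstance(value, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected}, got {type(value).__name__}"
            )
        if not validator(value):
            raise ValueError(f"config key {key!r}: invalid value {value!r}")
        config[key] = value
    for key, (_, default, _v) in _SCHEMA.items():
        config.setdefault(key, default)
    return config


def load_config_defaults() -> dict[str, Any]:
    """The fully defaulted configuration mapping."""
    return {key: default for key, (_, default, _v) in _SCHEMA.items()}


def simulation_config_from(config: dict[str, Any], seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a validated config mapping."""
    return SimulationConfig(
        n_trajectories=config["n_trajectories"],
        max_time=float(config["max_time"]),
        time_tick=float(config["time_tick"]),
        seed=config["seed"] if seed is None else seed,
        initial={k: float(v) for k, v in config["initial"].items()},
        tracked=config["tracked"],
    )


def load_model(path: str, cfg_path: str | None = None):
    """Load a model from BoolNet (``.bnet``/``.txt``) or MaBoSS (``.bnd``).

    For MaBoSS the companion ``.cfg`` is required (defaults to the same
    stem); returns ``(network, SimulationConfig | None)``.
    """
    if path.endswith(".bnd"):
        if cfg_path is None:
            cfg_path = path[:-4] + ".cfg"
        if not os.path.exists(cfg_path):
            raise FileNotFoundError(f"MaBoSS model needs a .cfg file ({cfg_path} not found)")
        with open(path) as fh:
            bnd_text = fh.read()
        with open(cfg_path) as fh:
            cfg_text = fh.read()
        return parse_maboss(bnd_text, cfg_text)
    with open(path) as fh:
        return parse_boolnet(fh.read()), None


def model_hash(network: BooleanNetwork) -> str:
    text = serialise_boolnet(network)
    rates = json.dumps(
        {"k_up": network.k_up, "k_down": network.k_down,
         "inputs": network.inputs, "outputs": network.outputs},
        sort_keys=True,
    )
    return hashlib.sha256((text + rates).encode()).hexdigest()[:16]


def config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    out_dir: str,
    command: str,
    seed: int,
    config: dict[str, Any],
    network: BooleanNetwork | None,
    outputs: list[str],
    extra: dict[str, Any] | None = None,
) -> str:
    """Write the JSON run manifest; exactly one per run."""
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "model_hash": model_hash(network) if network is not None else None,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [os.path.basename(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
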