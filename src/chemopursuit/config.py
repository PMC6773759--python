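"""Flat YAML configuration files mirroring the standard-parameter table.

A config file carries any subset of the scenario keys; unspecified
fields take the standard defaults, unknown keys and out-of-range values
are rejected by name.  ``preset`` selects a named strategy whose
individual parameters can then be overridden.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .engine import ScenarioConfig
from .presets import PRESETS
from .response import StrategyParams

__all__ = ["load_config", "save_config", "config_to_dict", "config_hash"]

_SCENARIO_KEYS = {
    "L_sys",
    "dt_sim",
    "T_sim",
    "N_tar",
    "r_tar",
    "r_imm",
    "D",
    "k",
    "ensemble",
    "v_tar",
    "eps_tar",
    "static_positions",
    "eliminate_on_contact",
    "seed",
}
_STRATEGY_KEYS = {"v_N", "eps_N", "v_A", "eps_A", "c_A0", "c_A1", "c_R1"}


def _build(raw: dict) -> ScenarioConfig:
    unknown = set(raw) - _SCENARIO_KEYS - _STRATEGY_KEYS - {"preset"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    preset = raw.pop("preset", None)
    base = PRESETS[preset.lower()].params.as_dict() if preset else None

    strat_over = {k: raw.pop(k) for k in list(raw) if k in _STRATEGY_KEYS}
    if base is None:
        base = ScenarioConfig().strategy.as_dict()
    base.update(strat_over)
    try:
        strategy = StrategyParams(**base)
    except ValueError as exc:
        raise ValueError(f"invalid strategy parameter: {exc}") from exc

    if "static_positions" in raw and raw["static_positions"] is not None:
        raw["static_positions"] = tuple(
            tuple(float(x) for x in p) for p in raw["static_positions"]
        )
    try:
        return ScenarioConfig(strategy=strategy, **raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid scenario configuration: {exc}") from exc


def load_config(path: str | Path | None = None, **overrides) -> ScenarioConfig:
    """Load a scenario from a YAML file (or from keyword overrides only)."""
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        raw.update(loaded)
    raw.update(overrides)
    return _build(raw)


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.update(d.pop("strategy"))
    return d


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: ScenarioConfig) -> str:
    """Short stable hash of the fully resolved configuration."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
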