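"""Relay configuration files (TOML or JSON) and their validation.

Schema (all keys optional except ``relay.layers``; unknown keys are rejected
with their full path):

    [relay]
    layers = 4
    totals = [10.0, 10.0, 10.0, 10.0]
    transfer_rates = [1.0, 1.0, 1.0]
    hydrolysis_rate = 1.0

    [crosstalk]
    act_rates = [0.0, 0.0, 0.0, 0.0]
    deact_rates = [0.0, 0.0, 0.0, 0.0]

    [bifunctional]
    enabled = false
    k_on = 1.0
    k_cat = 1.0

    [settings]
    # free-form experiment settings, passed through untouched

JSON files use the same structure with sections as objects.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from .model import RelaySpec, build_relay

__all__ = ["ConfigError", "load_config", "save_config"]

_RELAY_KEYS = {"layers", "totals", "transfer_rates", "hydrolysis_rate"}
_CROSSTALK_KEYS = {"act_rates", "deact_rates"}
_BIFUNCTIONAL_KEYS = {"enabled", "k_on", "k_cat"}
_SECTIONS = {"relay", "crosstalk", "bifunctional", "settings"}


class ConfigError(ValueError):
    """A configuration file violates the schema; the message names the key path."""


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        keys = ", ".join(f"{section}.{k}" for k in sorted(unknown))
        raise ConfigError(f"unknown configuration key(s): {keys}")


def load_config(path) -> tuple[RelaySpec, dict]:
    """Load and validate a relay configuration; returns (spec, settings).

    Missing optional keys fall back to the model defaults (totals 10, rates
    1.0, no cross-talk, bifunctional off).  Unknown sections or keys and
    invalid values fail loudly, naming the offending key path.
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a table/object")
    _check_keys("<root>", raw, _SECTIONS)
    relay = raw.get("relay", {})
    crosstalk = raw.get("crosstalk", {})
    bifunctional = raw.get("bifunctional", {})
    _check_keys("relay", relay, _RELAY_KEYS)
    _check_keys("crosstalk", crosstalk, _CROSSTALK_KEYS)
    _check_keys("bifunctional", bifunctional, _BIFUNCTIONAL_KEYS)

    if "layers" not in relay:
        raise ConfigError("relay.layers is required")
    overrides: dict = {}
    for key in ("totals", "transfer_rates", "hydrolysis_rate"):
        if key in relay:
            overrides[key] = relay[key]
    for key in _CROSSTALK_KEYS:
        if key in crosstalk:
            overrides[key] = crosstalk[key]
    if bifunctional.get("enabled", False):
        overrides["bifunctional"] = True
    for key in ("k_on", "k_cat"):
        if key in bifunctional:
            overrides[key] = bifunctional[key]
    try:
        spec = build_relay(int(relay["layers"]), overrides)
    except (ValueError, TypeError) as err:
        raise ConfigError(f"invalid configuration: {err}") from err
    return spec, dict(raw.get("settings", {}))


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ConfigError(f"cannot serialize value of type {type(value).__name__}")


def save_config(spec: RelaySpec, path, settings: dict | None = None) -> None:
    """Write a spec (and optional settings) as TOML or JSON, by file suffix."""
    doc = {
        "relay": {
            "layers": spec.n_layers,
            "totals": list(spec.totals),
            "transfer_rates": list(spec.transfer_rates),
            "hydrolysis_rate": spec.hydrolysis_rate,
        },
        "crosstalk": {
            "act_rates": list(spec.act_rates),
            "deact_rates": list(spec.deact_rates),
        },
        "bifunctional": {
            "enabled": spec.bifunctional,
            "k_on": spec.k_on,
            "k_cat": spec.k_cat,
        },
    }
    if settings:
        doc["settings"] = dict(settings)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    lines = []
    for section, table in doc.items():
        lines.append(f"[{section}]")
        for key, value in table.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    path.write_text("\n".join(lines))
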