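"""Flat YAML/JSON parameter configs with schema validation.

Schema (all keys optional; omitted keys take the published calibration):

.. code-block:: yaml

    dE_M_mV: -550.0
    dE_C_mV: -550.0
    dE_S_mV: -550.0
    Kd_M: 4.0e-5
    kf_perM_perS: 2.5e10
    kr_perS: 1.0e6
    kc_perS: 5.66e6
    temperature_C: 37.0
    n_half: 10
    consistent_binding_edges: false
    substrates:
      - {name: labelled, cyt_M: 5.0e-3, mat_M: 0.0}
      - {name: unlabelled, cyt_M: 0.0, mat_M: 5.0e-3}

Unknown keys are rejected; all violations are reported together.
"""

from __future__ import annotations

from numbers import Real
from pathlib import Path

import yaml

from .energy_model import ModelParams, Substrate

__all__ = ["ConfigError", "load_config", "dump_config", "params_to_dict", "params_from_dict"]

_SCALAR_KEYS = {
    "dE_M_mV": ("dE_M", Real),
    "dE_C_mV": ("dE_C", Real),
    "dE_S_mV": ("dE_S", Real),
    "Kd_M": ("Kd", Real),
    "kf_perM_perS": ("k_f", Real),
    "kr_perS": ("k_r", Real),
    "kc_perS": ("k_c", Real),
    "temperature_C": ("temperature", Real),
    "n_half": ("n_half", int),
    "consistent_binding_edges": ("consistent_binding_edges", bool),
}
_SUBSTRATE_KEYS = {"name", "cyt_M", "mat_M"}


class ConfigError(ValueError):
    """Raised with every schema violation found, newline-separated."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


def params_from_dict(data: dict | None) -> ModelParams:
    """Build validated ModelParams from a flat config mapping."""
    data = dict(data or {})
    errors: list[str] = []
    kwargs = {}
    for key, (attr, typ) in _SCALAR_KEYS.items():
        if key not in data:
            continue
        val = data.pop(key)
        if typ is bool:
            if not isinstance(val, bool):
                errors.append(f"{key}: expected boolean, got {val!r}")
                continue
        elif typ is int:
            if not isinstance(val, int) or isinstance(val, bool):
                errors.append(f"{key}: expected integer, got {val!r}")
                continue
        elif not isinstance(val, Real) or isinstance(val, bool):
            errors.append(f"{key}: expected number, got {val!r}")
            continue
        kwargs[attr] = val
    if "substrates" in data:
        subs_raw = data.pop("substrates")
        subs = []
        if not isinstance(subs_raw, list):
            errors.append(f"substrates: expected a list, got {subs_raw!r}")
        else:
            for i, entry in enumerate(subs_raw):
                if not isinstance(entry, dict):
                    errors.append(f"substrates[{i}]: expected a mapping, got {entry!r}")
                    continue
                unknown = set(entry) - _SUBSTRATE_KEYS
                missing = _SUBSTRATE_KEYS - set(entry)
                if unknown:
                    errors.append(f"substrates[{i}]: unknown keys {sorted(unknown)}")
                if missing:
                    errors.append(f"substrates[{i}]: missing keys {sorted(missing)}")
                if unknown or missing:
                    continue
                try:
                    subs.append(Substrate(str(entry["name"]), float(entry["cyt_M"]), float(entry["mat_M"])))
                except (TypeError, ValueError) as exc:
                    errors.append(f"substrates[{i}]: {exc}")
        if not errors:
            kwargs["substrates"] = tuple(subs)
    for key in data:
        errors.append(f"unknown key {key!r}")
    if errors:
        raise ConfigError(errors)
    try:
        return ModelParams(**kwargs)
    except ValueError as exc:
        # re-map internal attribute names back to config keys for the message
        msg = str(exc)
        for key, (attr, _) in _SCALAR_KEYS.items():
            msg = msg.replace(f"{attr} ", f"{key} ").replace(f"{attr}=", f"{key}=")
        raise ConfigError(msg.split("; ")) from None


def params_to_dict(params: ModelParams) -> dict:
    """Flat config mapping (inverse of params_from_dict up to defaults)."""
    return {
        "dE_M_mV": params.dE_M,
        "dE_C_mV": params.dE_C,
        "dE_S_mV": params.dE_S,
        "Kd_M": params.Kd,
        "kf_perM_perS": params.k_f,
        "kr_perS": params.k_r,
        "kc_perS": params.k_c,
        "temperature_C": params.temperature,
        "n_half": params.n_half,
        "consistent_binding_edges": params.consistent_binding_edges,
        "substrates": [
            {"name": s.name, "cyt_M": s.cyt_M, "mat_M": s.mat_M} for s in params.substrates
        ],
    }


def load_config(path) -> ModelParams:
    """Load and validate a YAML (or JSON, a YAML subset) config file.

    An empty file yields the full default (published) parameter set.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError([f"top level must be a mapping, got {type(data).__name__}"])
    return params_from_dict(data)


def dump_config(params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))
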