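"""Structured-text configuration for the two-population circuit.

The config is a YAML/JSON mapping mirroring the reference parameter
table::

    sizes:      {N_E: 8, N_I: 2}
    weights:    {J_EE: 10, J_EI: -70, J_IE: 70, J_II: -34}
    tau:        {E: 1.0, I: 1.0}
    activation: {nu_max: {E: 1.0, I: 1.0}, Lambda: {E: 2.0, I: 2.0}, V_T: {E: 2.0, I: 2.0}}
    noise:      {sigma: {E: 1.0e-4, I: 1.0e-4}, C_EE: 0.0, C_II: 0.0, C_EI: 0.0}

Every key is optional; omitted values fall back to the reference circuit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .network import (
    EXCITATORY,
    INHIBITORY,
    NetworkParams,
    NoiseModel,
    PopulationParams,
    SignConstraintError,
)

__all__ = ["load_config", "network_from_config", "noise_from_config", "default_config_dict", "ConfigError"]


class ConfigError(ValueError):
    pass


def default_config_dict() -> dict:
    return {
        "sizes": {"N_E": 8, "N_I": 2},
        "weights": {"J_EE": 10.0, "J_EI": -70.0, "J_IE": 70.0, "J_II": -34.0},
        "tau": {"E": 1.0, "I": 1.0},
        "activation": {
            "nu_max": {"E": 1.0, "I": 1.0},
            "Lambda": {"E": 2.0, "I": 2.0},
            "V_T": {"E": 2.0, "I": 2.0},
        },
        "noise": {
            "sigma": {"E": 1e-4, "I": 1e-4},
            "C_EE": 0.0,
            "C_II": 0.0,
            "C_EI": 0.0,
        },
    }


def load_config(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    return _merge(default_config_dict(), data)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _per_pop(v, key):
    if isinstance(v, dict):
        return float(v["E"]), float(v["I"])
    return float(v), float(v)


def network_from_config(cfg: dict) -> NetworkParams:
    try:
        sizes = cfg["sizes"]
        w = cfg["weights"]
        tau = cfg["tau"]
        act = cfg["activation"]
        nu = _per_pop(act["nu_max"], "nu_max")
        lam = _per_pop(act["Lambda"], "Lambda")
        vt = _per_pop(act["V_T"], "V_T")
        E = PopulationParams(EXCITATORY, int(sizes["N_E"]), float(tau["E"]), nu[0], lam[0], vt[0])
        I = PopulationParams(INHIBITORY, int(sizes["N_I"]), float(tau["I"]), nu[1], lam[1], vt[1])
        weights = np.array(
            [
                [float(w["J_EE"]), float(w["J_EI"])],
                [float(w["J_IE"]), float(w["J_II"])],
            ]
        )
        return NetworkParams((E, I), weights)
    except SignConstraintError as exc:
        raise ConfigError(f"invalid weights: {exc}") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def noise_from_config(cfg: dict) -> NoiseModel:
    try:
        nz = cfg["noise"]
        s = _per_pop(nz["sigma"], "sigma")
        cEE, cII, cEI = float(nz["C_EE"]), float(nz["C_II"]), float(nz["C_EI"])
        return NoiseModel(
            np.array(s), np.array([[cEE, cEI], [cEI, cII]])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid noise configuration: {exc}") from exc
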