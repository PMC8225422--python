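"""YAML configuration loading/saving with full validation.

An empty file (or missing section) means pure defaults -- the simulation
table of the study scenario.  Unknown keys are rejected with a message
listing the offending keys, so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .hh import HHParams
from .plasticity import PlasticityParams
from .simulate import SimulationConfig

__all__ = ["ConfigError", "load_config", "save_config", "config_to_dict", "config_from_dict"]


class ConfigError(ValueError):
    pass


_HH_KEYS = {"g_na", "g_k", "g_l", "e_na", "e_k", "e_l", "c_m", "i_ext", "v_rest"}
_PLASTICITY_KEYS = {"gamma", "radius", "epsilon", "update_period", "pair_product"}
_LATTICE_KEYS = {"global_l", "overlap_fraction"}
_INTEGRATOR_KEYS = {"rtol", "atol", "method"}
_TOP_KEYS = {
    "n",
    "t_end",
    "t_couple",
    "dt_output",
    "seed",
    "structural_mask",
    "init_mode",
    "v_init_low",
    "v_init_high",
    "i_ext_jitter",
    "position_jitter",
    "hh",
    "plasticity",
    "lattice",
    "structural",
    "integrator",
}
_STRUCTURAL_KEYS = {"global_l", "domains"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")


def config_from_dict(data: dict | None, structural=None) -> SimulationConfig:
    """Build a validated config; ``structural`` overrides the lattice layout
    (used when reloading traces whose network is not a lattice)."""
    data = dict(data or {})
    _check_keys(data, _TOP_KEYS, "config")

    hh_raw = dict(data.pop("hh", {}) or {})
    _check_keys(hh_raw, _HH_KEYS, "config.hh")
    plast_raw = dict(data.pop("plasticity", {}) or {})
    _check_keys(plast_raw, _PLASTICITY_KEYS, "config.plasticity")
    lattice_raw = dict(data.pop("lattice", {}) or {})
    _check_keys(lattice_raw, _LATTICE_KEYS, "config.lattice")
    integ_raw = dict(data.pop("integrator", {}) or {})
    _check_keys(integ_raw, _INTEGRATOR_KEYS, "config.integrator")
    struct_raw = dict(data.pop("structural", {}) or {})
    _check_keys(struct_raw, _STRUCTURAL_KEYS, "config.structural")
    if structural is None and struct_raw:
        from .domains import Domain, StructuralNetwork

        structural = StructuralNetwork(
            domains=[
                Domain(k, tuple(d["lower"]), tuple(d["upper"]))
                for k, d in enumerate(struct_raw["domains"])
            ],
            global_l=float(struct_raw.get("global_l", 100.0)),
        )

    try:
        return SimulationConfig(
            hh=HHParams(**hh_raw),
            plasticity=PlasticityParams(**plast_raw),
            structural=structural,
            **lattice_raw,
            **integ_raw,
            **data,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> SimulationConfig:
    """Read and validate a YAML config; empty file -> all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)


def config_to_dict(config: SimulationConfig) -> dict:
    """Round-trippable plain-dict form (includes explicit domain geometry)."""
    out = {
        "n": config.n,
        "t_end": config.t_end,
        "t_couple": config.t_couple,
        "dt_output": config.dt_output,
        "seed": config.seed,
        "structural_mask": config.structural_mask,
        "init_mode": config.init_mode,
        "v_init_low": config.v_init_low,
        "v_init_high": config.v_init_high,
        "i_ext_jitter": config.i_ext_jitter,
        "position_jitter": config.position_jitter,
        "hh": asdict(config.hh),
        "plasticity": asdict(config.plasticity),
        "lattice": {"global_l": config.global_l, "overlap_fraction": config.overlap_fraction},
        "integrator": {"rtol": config.rtol, "atol": config.atol, "method": config.method},
    }
    if config.structural is not None:
        out["structural"] = {
            "global_l": config.structural.global_l,
            "domains": [
                {"lower": list(d.lower), "upper": list(d.upper)}
                for d in config.structural.domains
            ],
        }
    return out


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
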