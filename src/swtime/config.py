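"""Scenario configuration files (YAML/JSON) and run provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .correlation import VarianceComponents, solve_components
from .design import Design, TreatmentStructure
from .simulate import SimulationScenario


class ConfigError(ValueError):
    """Malformed scenario or run configuration."""


def _require(cfg: dict, key: str, where: str):
    if key not in cfg:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return cfg[key]


def variance_components_from_config(cfg: dict) -> VarianceComponents:
    """Components either directly (tau_alpha_sq, tau_omega_sq, sigma_e_sq) or via
    (wpicc, cac, sigma_e_sq)."""
    if "wpicc" in cfg:
        return solve_components(
            float(cfg["wpicc"]), float(cfg.get("cac", 1.0)), float(_require(cfg, "sigma_e_sq", "variance_components"))
        )
    return VarianceComponents(
        tau_alpha_sq=float(_require(cfg, "tau_alpha_sq", "variance_components")),
        tau_omega_sq=float(_require(cfg, "tau_omega_sq", "variance_components")),
        sigma_e_sq=float(_require(cfg, "sigma_e_sq", "variance_components")),
    )


def scenario_from_config(cfg: dict) -> SimulationScenario:
    design = Design.from_config(dict(_require(cfg, "design", "scenario")))
    s_cfg = dict(_require(cfg, "structure", "scenario"))
    structure = TreatmentStructure(
        kind=_require(s_cfg, "kind", "structure"),
        effects=np.asarray(_require(s_cfg, "effects", "structure"), dtype=float),
    )
    vc = variance_components_from_config(dict(_require(cfg, "variance_components", "scenario")))
    trend = np.asarray(_require(cfg, "trend", "scenario"), dtype=float)
    return SimulationScenario(
        design=design,
        structure=structure,
        vc=vc,
        trend=trend,
        n_reps=int(cfg.get("n_reps", 200)),
        seed=int(cfg.get("seed", 0)),
    )


def load_scenario(path: str | Path) -> SimulationScenario:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping at the top level")
    return scenario_from_config(raw)


def scenario_hash(scenario: SimulationScenario) -> str:
    """Short stable digest of a scenario's full configuration."""
    blob = json.dumps(scenario.to_config(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_metadata(scenario: SimulationScenario, **extra) -> dict:
    from . import __version__

    meta = {
        "package": "swtime",
        "version": __version__,
        "scenario_hash": scenario_hash(scenario),
        "seed": scenario.seed,
        "scenario": scenario.to_config(),
    }
    meta.update(extra)
    return meta
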