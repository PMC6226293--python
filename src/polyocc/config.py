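"""Configuration loading and resolution.

A run is configured by a nested YAML or JSON mapping; every key has a
documented default, unknown keys are rejected by name, and the fully
resolved configuration (defaults + overrides) travels with every result as
provenance.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .lattice import ElementLayout
from .offdna import OffDnaParams
from .thermo import BindingEnergies, ThermoContext

__all__ = ["ConfigError", "RunConfig", "DEFAULTS", "load_config"]


class ConfigError(ValueError):
    """A configuration file could not be parsed or validated."""


DEFAULTS: dict[str, Any] = {
    "thermo": {"rt_kcal_per_mol": 0.593, "c0_molar": 1.0},
    "energies": {"alpha": -9.955, "beta": -5.837, "gamma_sam": 0.0},
    "element": {"n_sites": 24, "ets_positions": [1]},
    "offdna": {"kd_sam_molar": None, "n_max": 50, "m_species": 1},
    "scan": {
        "c_min_molar": 1e-12,
        "c_max_molar": 1.0,
        "points_per_decade": 25,
        "target": 0.5,
    },
    # pure annotation of the physiological concentration band; no defaults
    "physiological": {"c_min_molar": None, "c_max_molar": None},
}


def _merge(defaults: Mapping[str, Any], overrides: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        full = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {full!r}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"configuration section {full!r} must be a mapping")
            out[key] = _merge(defaults[key], value, full + ".")
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved configuration with typed accessors for the model objects."""

    data: dict[str, Any]

    def thermo(self) -> ThermoContext:
        t = self.data["thermo"]
        return ThermoContext(rt=t["rt_kcal_per_mol"], c0=t["c0_molar"])

    def energies(self, gamma_sam: float | None = None) -> BindingEnergies:
        e = self.data["energies"]
        gamma = e["gamma_sam"] if gamma_sam is None else gamma_sam
        return BindingEnergies(alpha=e["alpha"], beta=e["beta"], gamma_sam=gamma)

    def layout(self) -> ElementLayout:
        el = self.data["element"]
        return ElementLayout.from_positions(el["n_sites"], el["ets_positions"])

    def offdna(self, energies: BindingEnergies | None = None) -> OffDnaParams:
        o = self.data["offdna"]
        if o["kd_sam_molar"] is not None:
            return OffDnaParams(
                kd_sam=o["kd_sam_molar"], n_max=o["n_max"], m_species=o["m_species"]
            )
        if energies is None:
            energies = self.energies()
        return OffDnaParams.from_energies(
            energies, self.thermo(), n_max=o["n_max"], m_species=o["m_species"]
        )

    def resolved(self) -> dict[str, Any]:
        return copy.deepcopy(self.data)

    def provenance(self) -> dict[str, Any]:
        """Tool version plus the full resolved parameter set."""
        return {"tool": "polyocc", "version": __version__, "config": self.resolved()}


def load_config(path: "str | Path | None" = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a YAML/JSON config file, merge onto documented defaults, validate.

    Unknown keys are rejected by full dotted name; missing keys take their
    defaults; an empty (or absent) file yields the all-defaults configuration.
    Bound violations (e.g. ``offdna.n_max = 0``) are reported at load time.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"top level of {path} must be a mapping")
        raw = dict(loaded)
    if overrides:
        raw = _deep_update(raw, overrides)
    cfg = RunConfig(data=_merge(DEFAULTS, raw))
    # surface bound violations now, with the offending section named
    try:
        ctx = cfg.thermo()
        energies = cfg.energies()
        cfg.layout()
        cfg.offdna(energies)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    del ctx
    return cfg


def _deep_update(base: dict, extra: Mapping[str, Any]) -> dict:
    out = copy.deepcopy(base)
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def config_to_json(cfg: RunConfig) -> str:
    return json.dumps(cfg.provenance(), indent=2, sort_keys=True)
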