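"""Flat key-value configuration for every tunable threshold.

The config file is a YAML mapping with namespaced dotted keys, e.g.::

    seg.f_on: 0.1
    rules.bsa_ratio_max: 0.90
    tvv.target: 6.5
    sim.n_breaths: 300

Every threshold of the segmentation, rule, TVV-grading and simulator layers
appears here with its default, because all of them were tuned quantities in
the underlying clinical workflow and must stay user-visible.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .postprocess import TVVGradeScheme
from .rules import RuleParameters
from .segmentation import SegmentationParams
from .simulator import CohortSpec, PatientModel, VentilatorSettings

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "config_hash",
    "ConfigError",
    "segmentation_params",
    "rule_params",
    "tvv_scheme",
    "cohort_spec",
]


class ConfigError(KeyError):
    """Raised when a config key is missing or unknown."""


_PREFIXES = {
    "seg": SegmentationParams,
    "rules": RuleParameters,
    "tvv": TVVGradeScheme,
}

_SIM_FIELDS = {
    "sim.n_breaths": 300,
    "sim.dta_pct": 0.0,
    "sim.bsa_pct": 0.0,
    "sim.artifact_pct": 0.0,
    "sim.mode": "AC/VC",
    "sim.set_tv": 500.0,
    "sim.set_pressure": 12.0,
    "sim.peep": 5.0,
    "sim.rate": 20.0,
    "sim.i_time": 1.0,
    "sim.resistance": 10.0,
    "sim.compliance": 50.0,
    "sim.noise_sd": 0.02,
}


def default_config() -> dict:
    """The full flat default configuration."""
    cfg: dict = {}
    for prefix, cls in _PREFIXES.items():
        for f in dataclasses.fields(cls):
            cfg[f"{prefix}.{f.name}"] = f.default
    cfg.update(_SIM_FIELDS)
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Load a flat config file, filling unset keys with defaults.

    Unknown keys raise :class:`ConfigError` (a misspelled threshold silently
    falling back to its default would be worse than an error).
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a flat key-value mapping")
    unknown = set(user) - set(cfg)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg.update(user)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config, for provenance logging."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _build(prefix: str, cls, cfg: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        key = f"{prefix}.{f.name}"
        if key not in cfg:
            raise ConfigError(f"missing config key {key}")
        kwargs[f.name] = cfg[key]
    return cls(**kwargs)


def segmentation_params(cfg: dict) -> SegmentationParams:
    return _build("seg", SegmentationParams, cfg)


def rule_params(cfg: dict) -> RuleParameters:
    return _build("rules", RuleParameters, cfg)


def tvv_scheme(cfg: dict) -> TVVGradeScheme:
    return _build("tvv", TVVGradeScheme, cfg)


def cohort_spec(cfg: dict, seed: int = 0, patient_id: str = "sim") -> CohortSpec:
    """Build a simulator cohort spec from the ``sim.*`` keys."""
    try:
        settings = VentilatorSettings(
            mode=cfg["sim.mode"],
            set_tv=float(cfg["sim.set_tv"]),
            set_pressure=float(cfg["sim.set_pressure"]),
            peep=float(cfg["sim.peep"]),
            rate=float(cfg["sim.rate"]),
            i_time=float(cfg["sim.i_time"]),
        )
        patient = PatientModel(
            resistance=float(cfg["sim.resistance"]),
            compliance=float(cfg["sim.compliance"]),
            noise_sd=float(cfg["sim.noise_sd"]),
        )
        return CohortSpec(
            n_breaths=int(cfg["sim.n_breaths"]),
            dta_pct=float(cfg["sim.dta_pct"]),
            bsa_pct=float(cfg["sim.bsa_pct"]),
            artifact_pct=float(cfg["sim.artifact_pct"]),
            settings=settings,
            patient=patient,
            seed=seed,
            patient_id=patient_id,
        )
    except KeyError as exc:
        raise ConfigError(f"missing config key {exc.args[0]}") from exc
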