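"""YAML/JSON config loading mirroring the dataclass field names."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .engine import SequenceParams, SimulationConfig
from .lookup import CalibrationLine

__all__ = ["load_config", "seq_from_config", "sim_config_from_config", "r1_model_from_config"]


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def seq_from_config(cfg: dict) -> SequenceParams:
    """Build SequenceParams from a config dict (exact field names)."""
    keys = ("tr", "te", "flip_angle", "phase_increment", "field_strength")
    return SequenceParams(**{k: cfg[k] for k in keys if k in cfg})


def sim_config_from_config(cfg: dict) -> SimulationConfig:
    keys = ("n_isochromats", "n_excitations", "convergence_tol", "block", "seed")
    return SimulationConfig(**{k: cfg[k] for k in keys if k in cfg})


def r1_model_from_config(cfg):
    """A number -> fixed R1 (s^-1); a mapping -> CalibrationLine."""
    if isinstance(cfg, dict):
        return CalibrationLine(
            slope=cfg["slope"],
            intercept=cfg["intercept"],
            field_strength=cfg.get("field_strength", 1.5),
            source=cfg.get("source", "user"),
        )
    return float(cfg)
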