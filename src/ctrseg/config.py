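"""Run configuration: defaults, YAML overrides, provenance echo.

A run configuration is a nested mapping with one section per pipeline
stage.  Unknown keys are rejected so typos fail loudly, and the fully
resolved configuration is echoed into every output directory for
reproducibility.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS = {
    "seed": 0,
    "log_level": "INFO",
    "preprocess": {
        "size": 299,
        "clahe_clip": 2.0,
        "clahe_grid": 8,
    },
    "augment": {
        "enabled": True,
        "max_rotation_deg": 10.0,
        "zoom": 0.10,
    },
    "perturb": {
        "k": 3,
        "noise_low": -0.3,
        "noise_high": 0.3,
        "gamma_low": 0.6,
        "gamma_high": 0.9,
        "dropout_low": 0.1,
        "dropout_high": 0.7,
        "fdrop_invert": False,
    },
    "loss": {
        "unsup_pixel_mean": True,
        "dice_eps": 1e-6,
    },
    "ramp": {
        "length": 50,
    },
    "train": {
        "bs": 16,
        "learning_rate": 1e-3,
        "epochs": 100,
        "labeled_val_fraction": 0.2,
        "unlabeled_val_fraction": 0.1,
        "base_filters": 16,
        "depth": 5,
        "blocks_per_stage": 3,
        "cbam": True,
        "aux_decoders": 1,
        "bn_momentum": 0.99,
    },
    "ctr": {
        "pi": 0.50,
        "threshold": 0.5,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally layered with a YAML file and a dict."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def echo_config(cfg: dict, out_dir) -> Path:
    """Write the resolved configuration next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = out_dir / "config.resolved.yaml"
    target.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return target
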