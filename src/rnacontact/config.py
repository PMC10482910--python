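"""Run configuration: defaults, YAML loading, validation and overrides.

One global seed fans out into named per-module random streams; the
configuration used for a run is persisted alongside every artifact so any
output can be regenerated bit-identically.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "apply_overrides", "validate_config",
           "dump_config"]

DEFAULT_CONFIG = {
    "seed": 0,
    "backbone": {
        "n_blocks": 2,
        "n_heads": 4,
        "embed_dim": 64,
        "dropout": 0.1,
        "mlp_hidden": 128,
        "max_len": 512,
    },
    "tasks": {
        "active": ["inpainting"],
        "inpainting_fraction": 0.15,
        "jigsaw_chunks": 3,
        "jigsaw_classes": 4,
        "jigsaw_per_sequence": True,
        "bootstrap_fraction": 0.15,
        "bootstrap_level": "token",
        "contrastive_temperature": 0.1,
    },
    "pretrain": {
        "steps": 300,
        "learning_rate": 0.001,
        "max_E": 32,
        "max_L": 64,
    },
    "downstream": {
        "head": "logistic",
        "loss": "cross-entropy",
        "finetune": False,
        "learning_rate": 0.05,
        "max_epochs": 200,
        "finetune_epochs": 40,
        "early_stop_metric": "top_l",
        "boost_metric": "loss",
        "patience": 10,
        "holdout_fraction": 0.1,
        "rounds": 200,
        "max_depth": 3,
        "boost_learning_rate": 0.1,
        "max_E": 128,
    },
    "dca": {
        "identity_threshold": 0.8,
        "pseudocount": "meff",
        "apc": True,
    },
    "evaluation": {
        "threshold": 0.5,
        "min_separation": 4,
        "k_grid": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
                   1.2, 1.4, 1.6, 1.8, 2.0],
    },
    "simulate": {
        "n_train": 8,
        "n_test": 4,
        "L": 30,
        "E": 300,
        "n_pairs": 5,
        "beta": 3.0,
        "min_separation": 4,
    },
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict, reference: dict = DEFAULT_CONFIG, prefix: str = "") -> None:
    """Reject unknown fields, naming the offending key."""
    for key, value in cfg.items():
        path = f"{prefix}{key}"
        if key not in reference:
            raise ConfigError(f"unknown config field '{path}'")
        if isinstance(reference[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config field '{path}' must be a mapping")
            validate_config(value, reference[key], prefix=f"{path}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML file (validated)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        validate_config(user)
        cfg = _merge(cfg, user)
    return cfg


def apply_overrides(cfg: dict, overrides) -> dict:
    """Apply ``section.key=value`` overrides (values parsed as YAML)."""
    cfg = copy.deepcopy(cfg)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} must be key=value")
        dotted, raw = item.split("=", 1)
        keys = dotted.split(".")
        node = cfg
        ref = DEFAULT_CONFIG
        for k in keys[:-1]:
            if k not in ref or not isinstance(ref[k], dict):
                raise ConfigError(f"unknown config field '{dotted}'")
            node = node.setdefault(k, {})
            ref = ref[k]
        if keys[-1] not in ref:
            raise ConfigError(f"unknown config field '{dotted}'")
        node[keys[-1]] = yaml.safe_load(raw)
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
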