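"""Pipeline configuration: nested defaults, YAML I/O, strict key validation."""

from __future__ import annotations

import copy

import yaml

__all__ = ["default_config", "load_config", "merge_config", "normalize_config", "dump_config"]


def default_config() -> dict:
    return {
        "seed": 0,
        "psf": {"outer_radius": 2.0, "obscuration_ratio": 0.5, "half_width": 5},
        "restore": {
            "w_smooth": 0.1,
            "w_sparse": 0.02,
            "reweight_eps": 0.1,
            "max_iters": 500,
            "tol": 1e-6,
            "neighborhood": "8-connected",
            "sign": "mitotic",
            "outer_iters": 3,
            "zero_clip": 1e-5,
        },
        "candidates": {
            "min_area": 10,
            "threshold_frac": 0.1,
            "patch_size": 25,
            "from_original": True,
        },
        "coding": {"gamma1": 0.1, "gamma2": 0.1, "max_iters": 1000, "tol": 1e-8},
        "dict": {"M": 16, "T_max": None},
        "svm": {"C": 1.0, "class_weight": None},
        "simulate": {
            "frame_shape": [96, 96],
            "n_normal_cells": 8,
            "n_mitotic_cells": 5,
            "cell_radius_range": [3.0, 5.0],
            "amplitude_range": [0.6, 1.0],
            "background_level": 0.5,
            "noise_sigma": 0.01,
        },
    }


class ConfigError(ValueError):
    pass


def merge_config(base: dict, override: dict, _path: str = "") -> dict:
    """Deep-merge an override into the defaults, rejecting unknown keys."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        path = f"{_path}{key}"
        if key not in base:
            raise ConfigError(f"unknown config key: {path}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {path} must be a mapping")
            out[key] = merge_config(base[key], value, _path=path + ".")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and a dict of overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping at top level")
        cfg = merge_config(cfg, loaded)
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg


def normalize_config(cfg: dict) -> str:
    """Canonical YAML rendering (sorted keys); round-trips to itself."""
    return yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(normalize_config(cfg))
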