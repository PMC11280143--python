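"""Pipeline configuration: defaults, YAML loading, schema validation.

The configuration is a nested mapping validated against the default tree:
unknown keys raise a ``ConfigError`` naming the offending dotted key, and
leaf values must be type-compatible with the default.  All stage randomness
derives from the single root ``seed`` (split per stage via SeedSequence).
"""

from __future__ import annotations

from copy import deepcopy
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ConfigError", "DEFAULTS", "load_config", "validate_config", "stage_seed"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "synth": {
        "n_regions_per_hemisphere": 6,
        "ap_span_um": 3000.0,
        "n_per_group": 6,
        "baseline_ochief": 30.0,
        "baseline_cfos": 15.0,
        "dispersion": 2.0,
        "ochief_loss_multiplier": 0.1,
        "n_loss_regions": 2,
        "community_loading": 0.9,
        "n_communities": 2,
        "n_coupled_regions": 1,
        "coupled_amplitude": 1.5,
    },
    "segmentation": {
        "sd_multiplier_axon": 6.0,
        "sd_multiplier_spot": 2.0,
        "rolling_radius_px": 50,
        "spot_diameter_um": 10.0,
        "gaussian_sigma_px": 10.0,
    },
    "quantify": {
        "bin_width_um": 100.0,
        "density_exclusion": 800.0,
        "exclude_regions": [],
        "ochief_sd_multiplier": 13.0,
        "ochief_percentile": 20.0,
        "cfos_min_cells": 100.0,
    },
    "rewire": {
        "n_shuffles": 1000,
        "r_cut": 0.1,
        "null_pct": 95.0,
        "tendency_pct": 99.0,
    },
    "fosnet": {
        "p_max": 0.05,
        "r_abs_min": 0.0,
        "exact_p_n_max": 10,
    },
    "communities": {
        "r_grid": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        "n_shuffles": 1000,
        "n_restarts": 10,
    },
    "behavior": {"fps": 30.0},
    "qc": {"folds": 5, "n_shuffles": 1000},
}

_STAGE_ORDER = (
    "synth",
    "segmentation",
    "quantify",
    "structurewise",
    "rewire",
    "fosnet",
    "communities",
    "behavior",
    "qc",
)


def _merge(default: dict, user: dict, prefix: str = "") -> dict:
    out = deepcopy(default)
    for key, value in user.items():
        dotted = f"{prefix}{key}"
        if key not in default:
            raise ConfigError(f"unknown config key: {dotted!r}")
        if isinstance(default[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {dotted!r} must be a mapping")
            out[key] = _merge(default[key], value, prefix=f"{dotted}.")
        else:
            if isinstance(default[key], (int, float)) and not isinstance(value, bool):
                if not isinstance(value, (int, float)):
                    raise ConfigError(f"config key {dotted!r} must be numeric")
            elif not isinstance(value, type(default[key])):
                raise ConfigError(
                    f"config key {dotted!r} must be of type "
                    f"{type(default[key]).__name__}"
                )
            out[key] = value
    return out


def validate_config(user: dict) -> dict:
    """Merge a user mapping over the defaults, rejecting unknown keys."""
    cfg = _merge(DEFAULTS, user or {})
    for section in ("rewire", "communities", "qc"):
        if cfg[section]["n_shuffles"] <= 0:
            raise ConfigError(f"config key {section!r}.n_shuffles must be positive")
    if not cfg["communities"]["r_grid"]:
        raise ConfigError("config key 'communities.r_grid' must be nonempty")
    return cfg


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return validate_config({})
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(data)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the root seed."""
    if stage not in _STAGE_ORDER:
        raise ConfigError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(_STAGE_ORDER))
    return int(children[_STAGE_ORDER.index(stage)].generate_state(1)[0])
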