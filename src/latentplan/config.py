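"""Configuration: one nested mapping drives the whole pipeline.

Defaults describe the packaged desk-scale demo; a YAML file (and CLI
flags) override them section by section.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "grid_nrows": 60,
        "grid_ncols": 60,
        "cell_size": 1.0,
        "n_species": 40,
        "n_trees": 5,
        "pa_fraction": 0.12,
        "suppressed_fraction": 0.10,
        "autocorr_sigma": 6.0,
        "boundary_notch": True,
    },
    "true_model": {
        # coefficients on standardized predictors; unlisted predictors are 0
        "beta": {
            "body_mass_g": 0.5,
            "body_mass_g_sq": -0.25,
            "age_first_repro_d": 0.6,
            "litters_per_year": 0.3,
            "range_size_km2": -0.6,
            "fox_overlap": 0.5,
            "fire_total": 0.9,
            "fire_lds": -0.7,
        },
        "w_phylo": 0.4,
        "w_space": 0.2,
        "sigma2": 2.0,
        "spatial_range": 20.0,
        "suppression_shift": 3,
    },
    "risk": {
        "w_phylo": 0.4,
        "w_space": 0.2,
        "rho": 20.0,
        "skew_threshold": 1.0,
        "vif_threshold": 5.0,
        "delta_aicc": 2.0,
        "profile_covariance": False,
    },
    "planning": {
        "hex_side_km": 4.0,
        "w_floor": 0.01,
    },
    "targets": {
        "latent_threshold": 1.50,
        "status_threshold": 7,
        "area_proportion_range": [0.15, 0.7],
    },
    "prioritize": {
        "gap": 0.0,
    },
}


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config over the defaults, then apply ``overrides``."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, user)
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
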