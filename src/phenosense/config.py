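"""Run configuration: a single structured YAML file, validated and normalized.

Exactly one of the ``synthetic`` block (generator parameters) or the
``inputs`` block (paths to an observation CSV and a climate NetCDF) must be
active. Unknown keys are errors so typos cannot silently change a run.
"""

from __future__ import annotations

import copy

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "phenosense-run",
    "standardization": "species",
    "synthetic": None,
    "inputs": None,
    "model": {"candidates": ["global"]},
    "grids": {
        "surface": {
            "mat_range": [-5.0, 15.0],
            "mat_step": 0.2,
            "ivt_range": [0.4, 1.2],
            "ivt_step": 0.05,
        },
        "summary": {
            "mat_range": [-5.0, 15.0],
            "mat_step": 1.0,
            "ivt_range": [0.4, 1.2],
            "ivt_step": 0.1,
        },
    },
    "excluded_regions": None,  # None -> package defaults
    "ivt_levels": [0.4, 0.8, 1.2],
}

_SYNTHETIC_KEYS = {
    "n_per_species_continent",
    "years",
    "region",
    "gradients",
    "truth",
    "vegetative_fraction",
    "continent_weights",
}
_REGION_KEYS = {"lat_range", "lon_bands", "years"}
_INPUT_KEYS = {"observations", "climate"}
_GRID_KEYS = {"mat_range", "mat_step", "ivt_range", "ivt_step"}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _check_grid(grid: dict, where: str) -> None:
    _check_keys(grid, _GRID_KEYS, where)
    for axis in ("mat", "ivt"):
        lo, hi = grid[f"{axis}_range"]
        step = grid[f"{axis}_step"]
        if hi <= lo:
            raise ConfigError(f"{where}: {axis}_range must be increasing")
        if step <= 0 or step > (hi - lo):
            raise ConfigError(f"{where}: {axis}_step must be in (0, range]")


def validate_config(raw: dict) -> dict:
    """Merge with defaults and validate; returns the normalized config."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, set(DEFAULT_CONFIG), "config")
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in raw.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = copy.deepcopy(val)

    synth, inputs = cfg["synthetic"], cfg["inputs"]
    if (synth is None) == (inputs is None):
        raise ConfigError("exactly one of 'synthetic' or 'inputs' must be given")
    if synth is not None:
        _check_keys(synth, _SYNTHETIC_KEYS, "synthetic")
        synth.setdefault("n_per_species_continent", 2000)
        if "region" in synth and synth["region"] is not None:
            _check_keys(synth["region"], _REGION_KEYS, "synthetic.region")
    else:
        _check_keys(inputs, _INPUT_KEYS, "inputs")
        for k in _INPUT_KEYS:
            if k not in inputs:
                raise ConfigError(f"inputs.{k} is required")

    if cfg["standardization"] not in ("species", "species_continent", "global"):
        raise ConfigError(f"unknown standardization {cfg['standardization']!r}")
    _check_keys(cfg["model"], {"candidates"}, "model")
    if not cfg["model"]["candidates"]:
        raise ConfigError("model.candidates must be non-empty")
    for name, grid in cfg["grids"].items():
        if name not in ("surface", "summary"):
            raise ConfigError(f"unknown grid {name!r}")
        _check_grid(grid, f"grids.{name}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
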