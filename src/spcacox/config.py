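"""Run configuration: nested key-value defaults, YAML overrides, hashing.

Every analysis constant (winsorization bound 5, variance thresholds
0.90/0.92, the penalized-Cox lambda grid 0..2e-3 step 5e-5, alpha 0.05) is
a config default rather than a hard-coded value, and the SHA-256 hash of
the canonical config makes runs auditable.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULTS: dict = {
    "cohort": {
        "n_subjects": 20_000,
        "noise_effect": 0.0169,
        "event_fraction": 0.0395,
        "censor_time": 8.21,
    },
    "columns": {
        "time": "time",
        "event": "event",
        "exposures": None,  # None -> every column except id/time/event/covariates
        "covariates": ["age", "sex_male", "deprivation"],
        "id": "subject_id",
    },
    "preprocessing": {"winsor_bound": 5.0},
    "pca": {"variance_threshold": 0.90},
    "spca": {
        "penalty": "l1",
        "l1_ratio": 0.95,
        "lambda_grid": {"num": 30, "low": 1.0e-3, "high": 10.0},
        "order": "k_then_lambda",  # or "lambda_then_k"
        "support_tol": 1.0e-8,
    },
    "cox": {
        "alpha": 0.05,
        "lambda_grid": {"start": 0.0, "stop": 2.0e-3, "step": 5.0e-5},
    },
    "decile": {
        "composite_columns": ["noise_day_db", "noise_evening_db", "noise_night_db"],
        "variance_threshold": 0.92,
    },
    "attribution": {"alpha": 0.05, "max_support": 6},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
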