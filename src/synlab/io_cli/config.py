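"""Run configuration: YAML-backed, seed-explicit, unknown keys rejected."""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

log = logging.getLogger(__name__)

DEFAULTS: Dict = {
    "grammar": None,            # None -> package default grammar config
    "genome": {
        "n_contigs": 8,
        "contig_len": 250_000,
        "density": {"tead": 0.08, "tfap2c": 0.05, "tead_double": 0.04},
        "gc": 0.42,
        "pair_fraction": 0.6,
        "mismatch_prob": 0.25,
    },
    "profiles": {"depth": 0.01, "noise": "poisson"},
    "training": {
        "window": 1000,
        "background_fraction": 0.1,
        "filters": 32,
        "learning_rate": 0.01,
        "batch_size": 32,
        "max_epochs": 80,
        "patience": 12,
    },
    "predictor": "oracle",      # "oracle" | "trained"
    "attribution": {"n_refs": 20, "window": 400, "threshold_quantile": 0.97},
    "discovery": {"min_support": 8, "max_motifs": 6},
    "injection": {"n_backgrounds": 64, "window": 50,
                  "distances": [0, 10, 20, 30, 40, 60, 80, 100, 120, 150]},
    "islands": {"window": 500},
    "doublescan": {"pattern": "RMATTCCWD", "max_gap": 23},
    "seeds": {"genome": 1, "profiles": 2, "training": 3, "backgrounds": 4,
              "attribution": 5},
}


class ConfigError(ValueError):
    pass


def _merge(base: Dict, override: Dict, path: str = "") -> Dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key: {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict) and \
                key not in ("density",):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class RunConfig:
    values: Dict
    version: str = ""

    def __post_init__(self):
        if not self.version:
            from .. import __version__
            self.version = __version__
        for stage, seed in self.values["seeds"].items():
            if seed is None:
                self.values["seeds"][stage] = DEFAULTS["seeds"][stage]
                log.info("seed for %s not set; using default %d", stage,
                         DEFAULTS["seeds"][stage])

    def __getitem__(self, key):
        return self.values[key]

    def seed(self, stage: str) -> int:
        return int(self.values["seeds"][stage])

    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Optional[str] = None, overrides: Optional[Dict] = None
                ) -> RunConfig:
    """Resolve DEFAULTS <- YAML file <- overrides; unknown keys rejected."""
    values = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        values = _merge(values, user)
    if overrides:
        values = _merge(values, overrides)
    return RunConfig(values)
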