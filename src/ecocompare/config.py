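"""Run configuration, manifests and tidy CSV I/O."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

#: Recognised top-level config sections and scalar keys.
CONFIG_SCHEMA = {
    "scenario": str,
    "seed": int,
    "out_dir": str,
    "log_level": str,
    "grid": dict,
    "species": dict,
    "resource": dict,
    "pool": dict,
    "fishing": dict,
    "experiments": dict,
    "synthetic": dict,
}


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown top-level keys are rejected by name; missing optional
    sections default to empty dicts.  ``scenario`` and ``seed`` are
    required.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in CONFIG_SCHEMA.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise TypeError(f"config key {key!r} must be {typ.__name__}")
    for key in ("scenario", "seed"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    for section in ("grid", "species", "resource", "pool", "fishing",
                    "experiments", "synthetic"):
        cfg.setdefault(section, {})
    cfg.setdefault("out_dir", f"results/{cfg['scenario']}")
    cfg.setdefault("log_level", "INFO")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration dict."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class RunManifest:
    """Record of a pipeline stage: config hash, seed, version, timings and
    input/output checksums.  Written as JSON next to the stage outputs."""

    def __init__(self, cfg: dict, stage: str):
        from . import __version__

        self.data = {
            "stage": stage,
            "scenario": cfg.get("scenario"),
            "config_hash": config_hash(cfg),
            "seed": cfg.get("seed"),
            "version": __version__,
            "inputs": {},
            "outputs": {},
            "wall_time_s": None,
        }
        self._t0 = time.perf_counter()

    def add_input(self, path):
        self.data["inputs"][str(path)] = file_checksum(path)

    def add_output(self, path):
        self.data["outputs"][str(path)] = file_checksum(path)

    def write(self, out_dir: str | Path):
        self.data["wall_time_s"] = round(time.perf_counter() - self._t0, 3)
        out = Path(out_dir) / f"manifest_{self.data['stage']}.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(self.data, indent=2))
        return out


def write_tidy(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy long-format CSV (UTF-8, header, '.' decimal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def wide_from_tidy(df: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Year x group frame for one variable of a tidy trajectory table."""
    sub = df[df["variable"] == variable]
    return sub.pivot(index="year", columns="group", values="value")
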