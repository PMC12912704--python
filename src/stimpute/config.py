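"""Run configuration schema, parsing, hashing and provenance manifests."""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from .synthetic import SimConfig
from .training import TrainConfig


@dataclass
class MetricsConfig:
    leiden_resolution: float = 1.0
    n_pcs: int = 50
    n_neighbors: int = 15
    ssim_c1: float = 0.01
    ssim_c2: float = 0.03
    rmse_zscore: bool = True


@dataclass
class RunConfig:
    """Full hyperparameter schema for a run; defaults follow the published
    settings (1200 epochs, lr 1e-4, encoder hidden 128 x 2 layers, 6
    attention blocks with 16 heads, batch/width switched at 500 genes)."""

    seed: int = 0
    out_dir: str = "runs"
    normalization: str = "lognorm"   # {"lognorm", "raw"}
    target_sum: float = 1e4
    n_draws: int = 1
    n_steps: int | None = None       # reverse steps at inference; None = full T
    validation_step: int = 1500      # evaluation cadence (iterations), not T
    cv_folds: int = 5
    cv_mode: str = "scratch"
    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def validate(self) -> None:
        if self.normalization not in ("lognorm", "raw"):
            raise ValueError("normalization must be 'lognorm' or 'raw'")
        self.sim.validate()
        self.train.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _apply(dc, data: dict, path: str):
    valid = {f.name: f for f in dataclasses.fields(dc)}
    for key, val in data.items():
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {path}{key!r}{suffix}")
        current = getattr(dc, key)
        if dataclasses.is_dataclass(current) and isinstance(val, dict):
            _apply(current, val, path=f"{path}{key}.")
        else:
            setattr(dc, key, val)


def parse_config(
    path: str | None = None,
    overrides: dict | None = None,
) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus flag overrides.

    Unknown keys are rejected with the nearest valid key named; flag
    overrides win over file values.
    """
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _apply(cfg, data, path="")
    if overrides:
        _apply(cfg, overrides, path="")
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the full configuration (key order independent)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_provenance(
    cfg: RunConfig, inputs: list[str] | None = None, out_path: str | None = None
) -> dict:
    """JSON manifest with config hash, seed, version and input checksums."""
    from . import __version__

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {p: _file_checksum(p) for p in (inputs or [])},
    }
    if out_path is not None:
        os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
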