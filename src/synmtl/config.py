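"""Run configuration: documented defaults, YAML loading, seed fan-out.

Every tunable named in the package docs lives here with its default, so an
empty config file yields a fully specified run. A single top-level seed is
fanned out to per-stage seeds through a stable hash so stages can be rerun
in isolation and still reproduce.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import yaml

VARIANTS = ("full", "only-synergy", "only-sensitivity", "no-ae", "regression-only")


@dataclass(frozen=True)
class Config:
    # featurization
    fp_bits: int = 1024
    fp_radius: int = 3
    k_genes: int = 5000
    expression_is_log: bool = False
    zscore_scope: str = "global"  # "global" or "train-only" (leakage caveat in docs)
    # autoencoders
    c_drug: int = 128
    c_cell: int = 256
    ae_dropout: float = 0.2
    ae_epochs: int = 300
    ae_batch_size: int = 64
    ae_patience: int = 100
    # predictor
    shared_first_layer: int = 2048
    shared_first_layer_grid: Sequence[int] = (2048, 4096, 8192)
    learning_rate: float = 1e-4
    learning_rate_grid: Sequence[float] = (5e-4, 1e-4, 5e-5)
    dropout: float = 0.5
    batch_size: int = 128
    patience: int = 100
    max_epochs: int = 500
    n_folds: int = 5
    variant: str = "full"
    # labelers
    synergy_threshold: float = 30.0
    sensitivity_threshold: float = 50.0
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "fp_bits", "fp_radius", "k_genes", "c_drug", "c_cell",
            "shared_first_layer", "learning_rate", "batch_size", "max_epochs",
            "n_folds", "ae_epochs", "ae_batch_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config key {name!r} must be positive, got {getattr(self, name)}")
        for name in ("ae_dropout", "dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"config key {name!r} must be in [0, 1), got {getattr(self, name)}")
        for name in ("patience", "ae_patience"):
            if getattr(self, name) < 0:
                raise ValueError(f"config key {name!r} must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"config key 'variant' must be one of {VARIANTS}, got {self.variant!r}")
        if self.zscore_scope not in ("global", "train-only"):
            raise ValueError("config key 'zscore_scope' must be 'global' or 'train-only'")


def load_config(path: str | None = None, **overrides) -> Config:
    """Load a YAML config; unknown keys are rejected, missing keys defaulted."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("shared_first_layer_grid", "learning_rate_grid"):
        if key in data:
            data[key] = tuple(data[key])
    return Config(**data)


def save_config(cfg: Config, path: str) -> None:
    payload = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        payload[f.name] = list(v) if isinstance(v, tuple) else v
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def with_overrides(cfg: Config, **kw) -> Config:
    return replace(cfg, **kw)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
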