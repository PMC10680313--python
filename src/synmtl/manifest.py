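"""Run manifests: tie every output directory to config, seed and versions."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import fields
from datetime import datetime, timezone
from pathlib import Path

import numpy
import rdkit

from .config import Config
from .featurization import FEATURIZER_VERSION

MANIFEST_NAME = "run_manifest.json"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, cfg: Config,
                   inputs: dict[str, str | Path] | None = None) -> Path:
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_snapshot = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        cfg_snapshot[f.name] = list(v) if isinstance(v, tuple) else v
    payload = {
        "config": cfg_snapshot,
        "seed": cfg.seed,
        "versions": {
            "synmtl": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "rdkit": rdkit.__version__,
            "featurizer": FEATURIZER_VERSION,
        },
        "inputs": {name: {"path": str(p), "sha256": _digest(Path(p))}
                   for name, p in (inputs or {}).items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / MANIFEST_NAME
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def load_manifest(outdir: str | Path) -> dict:
    with open(Path(outdir) / MANIFEST_NAME) as fh:
        return json.load(fh)


def config_from_manifest(manifest: dict) -> Config:
    data = dict(manifest["config"])
    for key in ("shared_first_layer_grid", "learning_rate_grid"):
        if key in data:
            data[key] = tuple(data[key])
    return Config(**data)
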