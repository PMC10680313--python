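"""Checkpoint serialization for autoencoders and predictors.

Parameters go into a single ``.npz`` array container; the sidecar JSON
carries the spec fields, seed and featurizer provenance needed to rebuild
the network skeleton before loading the arrays into it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import _nn
from .autoencoder import AutoencoderSpec, TrainedAutoencoder, _build
from .featurization import FEATURIZER_VERSION
from .predictor import MultiTaskPredictor, PredictorSpec


def save_autoencoder(model: TrainedAutoencoder, outdir: str | Path,
                     name: str = "autoencoder") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = model.state()
    arrays = {f"encoder_{i}": a for i, a in enumerate(state["encoder"])}
    arrays.update({f"decoder_{i}": a for i, a in enumerate(state["decoder"])})
    np.savez(outdir / f"{name}.npz", **arrays)
    sidecar = {"spec": asdict(model.spec),
               "featurizer_version": FEATURIZER_VERSION,
               "training_curve": model.training_curve}
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(sidecar, fh)


def load_autoencoder(outdir: str | Path, name: str = "autoencoder") -> TrainedAutoencoder:
    outdir = Path(outdir)
    with open(outdir / f"{name}.json") as fh:
        sidecar = json.load(fh)
    spec = AutoencoderSpec(**sidecar["spec"])
    rng = np.random.default_rng(spec.seed)
    encoder, decoder = _build(spec, rng)
    with np.load(outdir / f"{name}.npz") as blob:
        enc = [blob[k] for k in sorted(blob.files, key=lambda s: (s.split("_")[0], int(s.split("_")[1])))
               if k.startswith("encoder_")]
        dec = [blob[k] for k in sorted(blob.files, key=lambda s: (s.split("_")[0], int(s.split("_")[1])))
               if k.startswith("decoder_")]
    _nn.set_state(encoder, enc)
    _nn.set_state(decoder, dec)
    model = TrainedAutoencoder(spec, encoder, decoder)
    model.training_curve = [tuple(t) for t in sidecar["training_curve"]]
    return model


def save_predictor(model: MultiTaskPredictor, outdir: str | Path,
                   name: str = "predictor") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {f"p_{i:04d}": a for i, a in enumerate(model.state())}
    np.savez(outdir / f"{name}.npz", **arrays)
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump({"spec": asdict(model.spec),
                   "featurizer_version": FEATURIZER_VERSION}, fh)


def load_predictor(outdir: str | Path, name: str = "predictor") -> MultiTaskPredictor:
    outdir = Path(outdir)
    with open(outdir / f"{name}.json") as fh:
        sidecar = json.load(fh)
    spec_d = sidecar["spec"]
    for key in ("shared_layer_sizes", "synergy_branch_sizes",
                "sensitivity_branch_sizes"):
        if spec_d.get(key) is not None:
            spec_d[key] = tuple(spec_d[key])
    model = MultiTaskPredictor(PredictorSpec(**spec_d))
    with np.load(outdir / f"{name}.npz") as blob:
        model.set_state([blob[k] for k in sorted(blob.files)])
    return model
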