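"""Pre-trained autoencoders for drug and cell-line feature compression.

Each autoencoder is a symmetric four-layer perceptron: two fully connected
encoder layers (ReLU between them, dropout after the encoder activation)
down to a low-dimensional code, and two decoder layers back to the input
width. Training minimizes the reconstruction loss

    L(x, x_hat) = sum_i ||x_i - x_hat_i||^2 / n

where n is the number of samples and the per-sample error is the sum of
squared elementwise differences. After pre-training the encoder is frozen
and used standalone to map features into the code space (dropout disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn


@dataclass(frozen=True)
class AutoencoderSpec:
    input_dim: int
    code_dim: int
    hidden_dim: int | None = None  # default: geometric mean rounded to a power of 2
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.code_dim < self.input_dim:
            raise ValueError("need 0 < code_dim < input_dim")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def resolved_hidden_dim(self) -> int:
        if self.hidden_dim is not None:
            return self.hidden_dim
        gm = np.sqrt(self.input_dim * self.code_dim)
        return int(2 ** round(np.log2(gm)))


@dataclass
class TrainedAutoencoder:
    spec: AutoencoderSpec
    encoder: _nn.Sequential
    decoder: _nn.Sequential
    training_curve: list[tuple[int, float]] = field(default_factory=list)

    @property
    def best_loss(self) -> float:
        return min(l for _, l in self.training_curve)

    def state(self) -> dict[str, list[np.ndarray]]:
        return {"encoder": _nn.get_state(self.encoder),
                "decoder": _nn.get_state(self.decoder)}


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over samples of the summed squared reconstruction error."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    n = x.shape[0]
    return float(((x - x_hat) ** 2).sum() / n)


def _build(spec: AutoencoderSpec, rng: np.random.Generator):
    h = spec.resolved_hidden_dim
    encoder = _nn.Sequential([
        _nn.Dense(spec.input_dim, h, rng),
        _nn.ReLU(),
        _nn.Dropout(spec.dropout_rate, rng),
        _nn.Dense(h, spec.code_dim, rng),
    ])
    decoder = _nn.Sequential([
        _nn.Dense(spec.code_dim, h, rng),
        _nn.ReLU(),
        _nn.Dense(h, spec.input_dim, rng),
    ])
    return encoder, decoder


def pretrain_autoencoder(features: np.ndarray, spec: AutoencoderSpec,
                         epochs: int = 300, batch_size: int = 64,
                         patience: int = 100, lr: float = 1e-3,
                         val_fraction: float = 0.1) -> TrainedAutoencoder:
    """Train the autoencoder; early stop on held-out reconstruction loss.

    Fully seeded: the spec seed drives the weight init, the train/validation
    split, batch shuffling and dropout, so two runs with the same inputs
    produce bit-identical parameters.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("features must be a matrix with >= 2 rows")
    if not np.isfinite(features).all():
        raise ValueError("features contain non-finite values")
    if features.shape[1] != spec.input_dim:
        raise ValueError(f"feature width {features.shape[1]} != spec.input_dim {spec.input_dim}")

    rng = np.random.default_rng(spec.seed)
    encoder, decoder = _build(spec, rng)
    params = encoder.params() + decoder.params()
    grads = encoder.grads() + decoder.grads()
    opt = _nn.Adam(params, grads, lr=lr)

    n = features.shape[0]
    n_val = max(1, int(round(val_fraction * n))) if n > 2 else 1
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train, x_val = features[train_idx], features[val_idx]

    def val_loss() -> float:
        code = encoder.forward(x_val, train=False)
        return reconstruction_loss(x_val, decoder.forward(code, train=False))

    model = TrainedAutoencoder(spec, encoder, decoder)
    best = np.inf
    best_state = None
    since_best = 0
    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        for start in range(0, len(x_train), batch_size):
            xb = x_train[order[start:start + batch_size]]
            code = encoder.forward(xb, train=True)
            xhat = decoder.forward(code, train=True)
            # d/dxhat of sum((x-xhat)^2)/n_batch
            grad = 2.0 * (xhat - xb) / len(xb)
            encoder.backward(decoder.backward(grad))
            opt.step()
        loss = val_loss()
        model.training_curve.append((epoch, loss))
        if loss < best:
            best = loss
            best_state = {"encoder": _nn.get_state(encoder), "decoder": _nn.get_state(decoder)}
            since_best = 0
        else:
            since_best += 1
            if since_best > patience:
                break
    if best_state is not None:
        _nn.set_state(encoder, best_state["encoder"])
        _nn.set_state(decoder, best_state["decoder"])
    return model


def encode(model: TrainedAutoencoder, features: np.ndarray) -> np.ndarray:
    """Map features into the code space (inference mode, deterministic)."""
    features = np.asarray(features, dtype=float)
    squeeze = features.ndim == 1
    if squeeze:
        features = features[None, :]
    if features.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"feature width {features.shape[1]} != encoder input width {model.spec.input_dim}")
    out = model.encoder.forward(features, train=False)
    return out[0] if squeeze else out
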