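"""Multi-task predictor: shared trunk plus synergy and sensitivity branches.

The shared module takes the concatenation of one encoded drug and one
encoded cell line through two fully connected layers, each followed by
batch normalization and ReLU. For a (drug_row, drug_col, cell) sample it is
applied twice, yielding representation I for (drug_row, cell) and
representation II for (drug_col, cell).

The synergy branch consumes I concatenated with II; the sensitivity branch
consumes I alone, so a drug's predicted monotherapy response is independent
of its combination partner by construction. Each branch is a stack of FC
layers with ReLU and dropout, topped by a linear regression head and a
two-unit softmax classification head. Because concatenation is order
sensitive, pair-level predictions average the two drug orders, which makes
the reported synergy outputs exactly symmetric in the drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _nn


@dataclass(frozen=True)
class PredictorSpec:
    drug_code_dim: int = 128
    cell_code_dim: int = 256
    shared_layer_sizes: tuple[int, int] | None = None  # default (2048, 1024)
    synergy_branch_sizes: tuple[int, ...] | None = None
    sensitivity_branch_sizes: tuple[int, ...] | None = None
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    use_synergy: bool = True
    use_sensitivity: bool = True
    use_classification: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for sizes in (self.shared_layer_sizes, self.synergy_branch_sizes,
                      self.sensitivity_branch_sizes):
            if sizes is not None and any(s <= 0 for s in sizes):
                raise ValueError("all layer sizes must be positive")
        if not (self.use_synergy or self.use_sensitivity):
            raise ValueError("at least one task branch must be enabled")

    @property
    def resolved_shared_sizes(self) -> tuple[int, int]:
        if self.shared_layer_sizes is not None:
            return tuple(self.shared_layer_sizes)
        return (2048, 1024)

    @property
    def shared_out(self) -> int:
        return self.resolved_shared_sizes[1]

    def _branch_default(self) -> tuple[int, ...]:
        s = self.shared_out
        return (s, max(1, s // 2), max(1, s // 4))

    @property
    def resolved_synergy_sizes(self) -> tuple[int, ...]:
        return tuple(self.synergy_branch_sizes or self._branch_default())

    @property
    def resolved_sensitivity_sizes(self) -> tuple[int, ...]:
        return tuple(self.sensitivity_branch_sizes or self._branch_default())


@dataclass
class PredictionBundle:
    """Pair-level outputs; sensitivity fields refer to the row (first) drug."""
    synergy_score: float | None
    synergy_prob: float | None
    sensitivity_score: float | None
    sensitivity_prob: float | None


def _branch(n_in: int, sizes: Sequence[int], dropout: float,
            rng: np.random.Generator) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    prev = n_in
    for s in sizes:
        layers += [_nn.Dense(prev, s, rng), _nn.ReLU(), _nn.Dropout(dropout, rng)]
        prev = s
    return _nn.Sequential(layers)


class MultiTaskPredictor:
    """The trainable network; all RNG flows from ``spec.seed``."""

    def __init__(self, spec: PredictorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.rng = rng
        s1, s2 = spec.resolved_shared_sizes
        n_in = spec.drug_code_dim + spec.cell_code_dim
        self.shared = _nn.Sequential([
            _nn.Dense(n_in, s1, rng), _nn.BatchNorm(s1), _nn.ReLU(),
            _nn.Dense(s1, s2, rng), _nn.BatchNorm(s2), _nn.ReLU(),
        ])
        self.syn_trunk = self.syn_score = self.syn_class = None
        self.sen_trunk = self.sen_score = self.sen_class = None
        if spec.use_synergy:
            sizes = spec.resolved_synergy_sizes
            self.syn_trunk = _branch(2 * s2, sizes, spec.dropout_rate, rng)
            self.syn_score = _nn.Dense(sizes[-1], 1, rng)
            if spec.use_classification:
                self.syn_class = _nn.Dense(sizes[-1], 2, rng)
        if spec.use_sensitivity:
            sizes = spec.resolved_sensitivity_sizes
            self.sen_trunk = _branch(s2, sizes, spec.dropout_rate, rng)
            self.sen_score = _nn.Dense(sizes[-1], 1, rng)
            if spec.use_classification:
                self.sen_class = _nn.Dense(sizes[-1], 2, rng)

    # -- parameter plumbing -------------------------------------------------
    def _components(self) -> list[_nn.Layer]:
        comps = [self.shared]
        for c in (self.syn_trunk, self.syn_score, self.syn_class,
                  self.sen_trunk, self.sen_score, self.sen_class):
            if c is not None:
                comps.append(c)
        return comps

    def params(self) -> list[np.ndarray]:
        return [p for c in self._components() for p in c.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for c in self._components() for g in c.grads()]

    def state(self) -> list[np.ndarray]:
        return [a for c in self._components() for a in _nn.get_state(c)]

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for c in self._components():
            n = len(_nn.get_state(c))
            _nn.set_state(c, [next(it) for _ in range(n)])

    # -- forward passes -----------------------------------------------------
    def shared_forward(self, drug_code: np.ndarray, cell_code: np.ndarray,
                       train: bool = False) -> np.ndarray:
        drug_code = np.atleast_2d(np.asarray(drug_code, dtype=float))
        cell_code = np.atleast_2d(np.asarray(cell_code, dtype=float))
        if drug_code.shape[1] != self.spec.drug_code_dim:
            raise ValueError(f"drug code width {drug_code.shape[1]} != {self.spec.drug_code_dim}")
        if cell_code.shape[1] != self.spec.cell_code_dim:
            raise ValueError(f"cell code width {cell_code.shape[1]} != {self.spec.cell_code_dim}")
        return self.shared.forward(np.hstack([drug_code, cell_code]), train)

    def _head_forward(self, trunk, score_head, class_head, x, train):
        h = trunk.forward(x, train)
        scores = score_head.forward(h, train)[:, 0]
        probs = None
        if class_head is not None:
            probs = _nn.softmax(class_head.forward(h, train))
        return scores, probs

    def synergy_forward(self, rep_I: np.ndarray, rep_II: np.ndarray,
                        train: bool = False):
        """Order-sensitive synergy outputs for representations I and II."""
        if self.syn_trunk is None:
            raise RuntimeError("this model variant has no synergy branch")
        rep_I = np.atleast_2d(rep_I)
        rep_II = np.atleast_2d(rep_II)
        if rep_I.shape != rep_II.shape:
            raise ValueError("representation shapes differ")
        return self._head_forward(self.syn_trunk, self.syn_score, self.syn_class,
                                  np.hstack([rep_I, rep_II]), train)

    def sensitivity_forward(self, rep_I: np.ndarray, train: bool = False):
        if self.sen_trunk is None:
            raise RuntimeError("this model variant has no sensitivity branch")
        return self._head_forward(self.sen_trunk, self.sen_score, self.sen_class,
                                  np.atleast_2d(rep_I), train)

    # -- pair-level prediction ----------------------------------------------
    def predict_batch(self, drug_row_codes: np.ndarray, drug_col_codes: np.ndarray,
                      cell_codes: np.ndarray) -> dict[str, np.ndarray | None]:
        """Order-averaged synergy and row-drug sensitivity for a batch of triples."""
        rep_I = self.shared_forward(drug_row_codes, cell_codes, train=False)
        rep_II = self.shared_forward(drug_col_codes, cell_codes, train=False)
        out: dict[str, np.ndarray | None] = {
            "synergy_score": None, "synergy_prob": None,
            "sensitivity_score": None, "sensitivity_prob": None,
        }
        if self.syn_trunk is not None:
            s_ab, p_ab = self.synergy_forward(rep_I, rep_II)
            s_ba, p_ba = self.synergy_forward(rep_II, rep_I)
            out["synergy_score"] = (s_ab + s_ba) / 2.0
            if p_ab is not None:
                out["synergy_prob"] = (p_ab[:, 1] + p_ba[:, 1]) / 2.0
        if self.sen_trunk is not None:
            s, p = self.sensitivity_forward(rep_I)
            out["sensitivity_score"] = s
            if p is not None:
                out["sensitivity_prob"] = p[:, 1]
        return out

    def predict_pair(self, drugA_code: np.ndarray, drugB_code: np.ndarray,
                     cell_code: np.ndarray) -> PredictionBundle:
        """Single-pair convenience wrapper; sensitivity is drug A's."""
        res = self.predict_batch(np.atleast_2d(drugA_code),
                                 np.atleast_2d(drugB_code),
                                 np.atleast_2d(cell_code))
        pick = lambda a: None if a is None else float(a[0])
        return PredictionBundle(
            synergy_score=pick(res["synergy_score"]),
            synergy_prob=pick(res["synergy_prob"]),
            sensitivity_score=pick(res["sensitivity_score"]),
            sensitivity_prob=pick(res["sensitivity_prob"]),
        )
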