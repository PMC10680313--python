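"""Multi-task training: dual fold plans, leakage-filtered loss, CV driver.

Two independent five-fold partitions control generalization testing:

* combination folds — every unordered drug pair lives in exactly one fold,
  so test combinations are never seen during training;
* drug folds — every drug lives in exactly one fold, used only by the
  monotherapy-sensitivity task.

During training each synergy sample enters in both drug orders. Within a
mini-batch the synergy losses are computed on all rows, while sensitivity
rows whose row-drug belongs to the held-out drug fold are filtered out
before the sensitivity losses are computed (the leakage filter). The total
objective is the unweighted sum of four terms: MSE and binary cross
entropy for each task. Early stopping monitors the total validation loss
with a patience window, keeping the checkpoint with the lowest loss.

At test time the roles flip: synergy is predicted for every sample of the
held-out combination fold, and sensitivity is predicted only for row-drugs
of the held-out drug fold, so no drug is ever evaluated on a monotherapy
response it was trained on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _nn
from .evaluation import (classification_metrics, label_sensitivity,
                         label_synergy, regression_metrics, POSITIVE)
from .predictor import MultiTaskPredictor, PredictorSpec

EPS_PROB = 1e-7


# ---------------------------------------------------------------------------
# samples and fold plans

def pair_key(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Canonical unordered key for a drug pair."""
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


@dataclass
class SynergySample:
    drug_row: str
    drug_col: str
    cell_id: str
    loewe_score: float
    label: str = ""
    combo_fold: int = -1

    def __post_init__(self):
        if not self.label:
            self.label = label_synergy(self.loewe_score)


@dataclass
class SensitivitySample:
    drug_id: str
    cell_id: str
    ri_score: float
    label: str = ""
    drug_fold: int = -1

    def __post_init__(self):
        if not self.label:
            self.label = label_sensitivity(self.ri_score)


@dataclass(frozen=True)
class LossBreakdown:
    mse_syn: float
    mse_sen: float
    bce_syn: float
    bce_sen: float

    @property
    def total(self) -> float:
        return self.mse_syn + self.mse_sen + self.bce_syn + self.bce_sen


@dataclass
class CvPlan:
    combo_folds: dict[tuple[str, str], int] = field(default_factory=dict)
    drug_folds: dict[str, int] = field(default_factory=dict)
    n_folds: int = 5


def _deal_round_robin(keys: list, n_folds: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    keys = sorted(keys)
    order = rng.permutation(len(keys))
    return {keys[j]: i % n_folds for i, j in enumerate(order)}


def assign_combo_folds(samples: list[SynergySample], n_folds: int = 5,
                       seed: int = 0) -> CvPlan:
    """Shuffle unordered pairs and deal them round-robin into folds."""
    pairs = sorted({pair_key(s.drug_row, s.drug_col) for s in samples})
    if len(pairs) < n_folds:
        raise ValueError(f"only {len(pairs)} distinct pairs for {n_folds} folds")
    plan = CvPlan(combo_folds=_deal_round_robin(pairs, n_folds, seed),
                  n_folds=n_folds)
    for s in samples:
        s.combo_fold = plan.combo_folds[pair_key(s.drug_row, s.drug_col)]
    return plan


def assign_drug_folds(drugs: list[str], n_folds: int = 5, seed: int = 0,
                      plan: CvPlan | None = None) -> CvPlan:
    """Partition drugs into folds for the sensitivity task."""
    unique = sorted(set(drugs))
    if len(unique) < n_folds:
        raise ValueError(f"only {len(unique)} distinct drugs for {n_folds} folds")
    if plan is None:
        plan = CvPlan(n_folds=n_folds)
    plan.drug_folds = _deal_round_robin(unique, n_folds, seed)
    return plan


# ---------------------------------------------------------------------------
# loss primitives

def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Binary cross entropy on the positive-class probability.

    Probabilities are clamped away from {0, 1} so the logs stay finite.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    p = np.clip(y_hat, EPS_PROB, 1.0 - EPS_PROB)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y - y_hat) ** 2))


def total_loss(predictions: dict, targets: dict) -> LossBreakdown:
    """Four-term objective on a (possibly leakage-filtered) batch.

    Keys: ``syn_score``/``syn_prob`` and ``sen_score``/``sen_prob`` in
    ``predictions``; ``syn_score``/``syn_label`` and ``sen_score``/
    ``sen_label`` in ``targets``. The sensitivity sub-batch may be empty,
    contributing exactly zero to its two terms; the synergy sub-batch may
    not. Probability entries may be absent for regression-only variants.
    """
    syn_true = np.asarray(targets["syn_score"], dtype=float)
    if syn_true.size == 0:
        raise ValueError("a training batch must carry synergy targets")
    mse_syn = mse_loss(syn_true, predictions["syn_score"])
    bce_syn = 0.0
    if predictions.get("syn_prob") is not None:
        bce_syn = bce_loss(np.asarray(targets["syn_label"], dtype=float),
                           predictions["syn_prob"])
    sen_true = np.asarray(targets.get("sen_score", []), dtype=float)
    mse_sen = bce_sen = 0.0
    if sen_true.size:
        mse_sen = mse_loss(sen_true, predictions["sen_score"])
        if predictions.get("sen_prob") is not None:
            bce_sen = bce_loss(np.asarray(targets["sen_label"], dtype=float),
                               predictions["sen_prob"])
    return LossBreakdown(mse_syn=mse_syn, mse_sen=mse_sen,
                         bce_syn=bce_syn, bce_sen=bce_sen)


# ---------------------------------------------------------------------------
# encoded dataset and ordered-row views

@dataclass
class EncodedDataset:
    """Everything the trainer consumes: code matrices and labeled samples."""
    drug_codes: np.ndarray            # n_drugs x c_drug
    cell_codes: np.ndarray            # n_cells x c_cell
    drug_ids: list[str]
    cell_ids: list[str]
    samples: list[SynergySample]
    sensitivity: dict[tuple[str, str], SensitivitySample]
    plan: CvPlan

    def __post_init__(self):
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    def drug_idx(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def cell_idx(self, cell_id: str) -> int:
        try:
            return self._cell_index[cell_id]
        except KeyError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None


@dataclass
class OrderedRows:
    """Order-duplicated synergy rows with aligned sensitivity targets.

    ``sen_mask`` marks rows whose (row-drug, cell) has a known monotherapy
    response; the leakage filter only ever shrinks this mask.
    """
    row_idx: np.ndarray
    col_idx: np.ndarray
    cell_idx: np.ndarray
    syn_score: np.ndarray
    syn_label: np.ndarray          # 0/1 floats
    drug_row_fold: np.ndarray      # drug-fold of the row drug (-1 if unassigned)
    sen_mask: np.ndarray           # bool
    sen_score: np.ndarray          # nan where sen_mask is False
    sen_label: np.ndarray

    def __len__(self) -> int:
        return len(self.row_idx)

    def take(self, idx: np.ndarray) -> "OrderedRows":
        return OrderedRows(*(getattr(self, f)[idx] for f in (
            "row_idx", "col_idx", "cell_idx", "syn_score", "syn_label",
            "drug_row_fold", "sen_mask", "sen_score", "sen_label")))


def build_ordered_rows(data: EncodedDataset,
                       samples: list[SynergySample]) -> OrderedRows:
    """Duplicate each sample into both drug orders; targets are unchanged."""
    cols = {f: [] for f in ("row_idx", "col_idx", "cell_idx", "syn_score",
                            "syn_label", "drug_row_fold", "sen_mask",
                            "sen_score", "sen_label")}
    for s in samples:
        for a, b in ((s.drug_row, s.drug_col), (s.drug_col, s.drug_row)):
            cols["row_idx"].append(data.drug_idx(a))
            cols["col_idx"].append(data.drug_idx(b))
            cols["cell_idx"].append(data.cell_idx(s.cell_id))
            cols["syn_score"].append(s.loewe_score)
            cols["syn_label"].append(1.0 if s.label == POSITIVE else 0.0)
            cols["drug_row_fold"].append(data.plan.drug_folds.get(a, -1))
            sen = data.sensitivity.get((a, s.cell_id))
            cols["sen_mask"].append(sen is not None)
            cols["sen_score"].append(np.nan if sen is None else sen.ri_score)
            cols["sen_label"].append(
                np.nan if sen is None else (1.0 if sen.label == POSITIVE else 0.0))
    arr = {k: np.asarray(v) for k, v in cols.items()}
    arr["sen_mask"] = arr["sen_mask"].astype(bool)
    return OrderedRows(**arr)


def leakage_filter(rows: OrderedRows, held_out_drug_fold: int | None) -> OrderedRows:
    """Drop held-out-fold drugs from the sensitivity sub-batch only."""
    if held_out_drug_fold is None:
        return rows
    out = rows.take(np.arange(len(rows)))
    out.sen_mask = rows.sen_mask & (rows.drug_row_fold != held_out_drug_fold)
    return out


# ---------------------------------------------------------------------------
# the training loop

@dataclass(frozen=True)
class TrainOptions:
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 100
    seed: int = 0
    held_out_drug_fold: int | None = None
    verbose: bool = False


def _softmax_ce_grad(probs: np.ndarray, labels01: np.ndarray) -> np.ndarray:
    onehot = np.stack([1.0 - labels01, labels01], axis=1)
    return (probs - onehot) / len(labels01)


def _train_step(model: MultiTaskPredictor, data: EncodedDataset,
                batch: OrderedRows) -> LossBreakdown:
    spec = model.spec
    n = len(batch)
    x_row = np.hstack([data.drug_codes[batch.row_idx], data.cell_codes[batch.cell_idx]])
    x_col = np.hstack([data.drug_codes[batch.col_idx], data.cell_codes[batch.cell_idx]])
    rep = model.shared.forward(np.vstack([x_row, x_col]), train=True)
    rep_I, rep_II = rep[:n], rep[n:]
    g_I = np.zeros_like(rep_I)
    g_II = np.zeros_like(rep_II)

    mse_syn = bce_syn = mse_sen = bce_sen = 0.0
    if spec.use_synergy:
        h = model.syn_trunk.forward(np.hstack([rep_I, rep_II]), train=True)
        scores = model.syn_score.forward(h, train=True)[:, 0]
        mse_syn = mse_loss(batch.syn_score, scores)
        g_h = model.syn_score.backward((2.0 * (scores - batch.syn_score) / n)[:, None])
        if model.syn_class is not None:
            probs = _nn.softmax(model.syn_class.forward(h, train=True))
            bce_syn = bce_loss(batch.syn_label, probs[:, 1])
            g_h = g_h + model.syn_class.backward(_softmax_ce_grad(probs, batch.syn_label))
        g_cat = model.syn_trunk.backward(g_h)
        s2 = rep_I.shape[1]
        g_I += g_cat[:, :s2]
        g_II += g_cat[:, s2:]

    if spec.use_sensitivity and batch.sen_mask.any():
        m = batch.sen_mask
        h = model.sen_trunk.forward(rep_I[m], train=True)
        scores = model.sen_score.forward(h, train=True)[:, 0]
        y = batch.sen_score[m]
        mse_sen = mse_loss(y, scores)
        g_h = model.sen_score.backward((2.0 * (scores - y) / m.sum())[:, None])
        if model.sen_class is not None:
            probs = _nn.softmax(model.sen_class.forward(h, train=True))
            bce_sen = bce_loss(batch.sen_label[m], probs[:, 1])
            g_h = g_h + model.sen_class.backward(
                _softmax_ce_grad(probs, batch.sen_label[m]))
        g_I[m] += model.sen_trunk.backward(g_h)

    model.shared.backward(np.vstack([g_I, g_II]))
    return LossBreakdown(mse_syn, mse_sen, bce_syn, bce_sen)


def evaluate_loss(model: MultiTaskPredictor, data: EncodedDataset,
                  rows: OrderedRows, chunk: int = 4096) -> LossBreakdown:
    """Total-objective breakdown in inference mode (no dropout, running BN)."""
    spec = model.spec
    syn_p, syn_pr, sen_p, sen_pr = [], [], [], []
    for start in range(0, len(rows), chunk):
        b = rows.take(np.arange(start, min(start + chunk, len(rows))))
        x_row = np.hstack([data.drug_codes[b.row_idx], data.cell_codes[b.cell_idx]])
        x_col = np.hstack([data.drug_codes[b.col_idx], data.cell_codes[b.cell_idx]])
        rep_I = model.shared.forward(x_row, train=False)
        rep_II = model.shared.forward(x_col, train=False)
        if spec.use_synergy:
            s, p = model.synergy_forward(rep_I, rep_II)
            syn_p.append(s)
            if p is not None:
                syn_pr.append(p[:, 1])
        if spec.use_sensitivity and b.sen_mask.any():
            s, p = model.sensitivity_forward(rep_I[b.sen_mask])
            sen_p.append(s)
            if p is not None:
                sen_pr.append(p[:, 1])
    mse_syn = bce_syn = mse_sen = bce_sen = 0.0
    if spec.use_synergy:
        syn_pred = np.concatenate(syn_p)
        mse_syn = mse_loss(rows.syn_score, syn_pred)
        if syn_pr:
            bce_syn = bce_loss(rows.syn_label, np.concatenate(syn_pr))
    if spec.use_sensitivity and sen_p:
        sen_pred = np.concatenate(sen_p)
        m = rows.sen_mask
        mse_sen = mse_loss(rows.sen_score[m], sen_pred)
        if sen_pr:
            bce_sen = bce_loss(rows.sen_label[m], np.concatenate(sen_pr))
    return LossBreakdown(mse_syn, mse_sen, bce_syn, bce_sen)


@dataclass
class TrainingResult:
    model: MultiTaskPredictor
    history: list[LossBreakdown]       # validation breakdown per epoch
    best_epoch: int
    best_loss: float


def train_model(data: EncodedDataset, train_samples: list[SynergySample],
                val_samples: list[SynergySample], spec: PredictorSpec,
                opts: TrainOptions) -> TrainingResult:
    """Fit the multi-task model with early stopping on validation loss."""
    model = MultiTaskPredictor(spec)
    opt = _nn.Adam(model.params(), model.grads(), lr=spec.learning_rate)
    rng = np.random.default_rng(opts.seed)

    train_rows = leakage_filter(build_ordered_rows(data, train_samples),
                                opts.held_out_drug_fold)
    val_rows = leakage_filter(build_ordered_rows(data, val_samples),
                              opts.held_out_drug_fold)

    history: list[LossBreakdown] = []
    best = np.inf
    best_epoch = -1
    best_state = model.state()
    since_best = 0
    for epoch in range(opts.max_epochs):
        order = rng.permutation(len(train_rows))
        for start in range(0, len(train_rows), opts.batch_size):
            batch = train_rows.take(order[start:start + opts.batch_size])
            step_loss = _train_step(model, data, batch)
            if not np.isfinite(step_loss.total):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {step_loss}")
            opt.step()
        val = evaluate_loss(model, data, val_rows)
        if not np.isfinite(val.total):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}: {val}")
        history.append(val)
        if opts.verbose:
            print(f"epoch {epoch}: val total {val.total:.4f}")
        if val.total < best:
            best = val.total
            best_epoch = epoch
            best_state = model.state()
            since_best = 0
        else:
            since_best += 1
            if since_best > opts.patience:
                break
    model.set_state(best_state)
    return TrainingResult(model=model, history=history,
                          best_epoch=best_epoch, best_loss=float(best))


# ---------------------------------------------------------------------------
# grid search

def grid_search(data: EncodedDataset, train_samples: list[SynergySample],
                val_samples: list[SynergySample], base_spec: PredictorSpec,
                first_layer_grid=(2048, 4096, 8192),
                lr_grid=(5e-4, 1e-4, 5e-5),
                opts: TrainOptions = TrainOptions()):
    """Exhaustive search over first-layer size x learning rate.

    Ties on validation loss prefer the lower learning rate, then the
    smaller first layer.
    """
    rows = []
    for size, lr in itertools.product(first_layer_grid, lr_grid):
        spec = replace(base_spec, shared_layer_sizes=(size, max(1, size // 2)),
                       learning_rate=lr)
        result = train_model(data, train_samples, val_samples, spec, opts)
        rows.append({"first_layer": size, "learning_rate": lr,
                     "val_loss": result.best_loss})
    table = pd.DataFrame(rows)
    best = select_best_cell(table)
    best_spec = replace(base_spec,
                        shared_layer_sizes=(int(best.first_layer),
                                            max(1, int(best.first_layer) // 2)),
                        learning_rate=float(best.learning_rate))
    return best_spec, table


def select_best_cell(table: pd.DataFrame) -> pd.Series:
    """Lowest validation loss; ties prefer lower lr, then smaller layer."""
    ranked = table.sort_values(["val_loss", "learning_rate", "first_layer"],
                               kind="stable")
    return ranked.iloc[0]


# ---------------------------------------------------------------------------
# cross-validation driver

def _predict_synergy(model, data, samples, chunk=4096) -> pd.DataFrame:
    rows = []
    for start in range(0, len(samples), chunk):
        part = samples[start:start + chunk]
        r = np.array([data.drug_idx(s.drug_row) for s in part])
        c = np.array([data.drug_idx(s.drug_col) for s in part])
        k = np.array([data.cell_idx(s.cell_id) for s in part])
        out = model.predict_batch(data.drug_codes[r], data.drug_codes[c],
                                  data.cell_codes[k])
        for i, s in enumerate(part):
            rows.append({
                "drug_row": s.drug_row, "drug_col": s.drug_col,
                "cell_id": s.cell_id, "fold": s.combo_fold,
                "y_true": s.loewe_score,
                "y_pred": float(out["synergy_score"][i]),
                "label_true": 1 if s.label == POSITIVE else 0,
                "prob_pred": (float(out["synergy_prob"][i])
                              if out["synergy_prob"] is not None else np.nan),
            })
    return pd.DataFrame(rows)


def _predict_sensitivity(model, data, pairs: list[tuple[str, str]],
                         fold: int) -> pd.DataFrame:
    rows = []
    if pairs:
        r = np.array([data.drug_idx(d) for d, _ in pairs])
        k = np.array([data.cell_idx(c) for _, c in pairs])
        rep_I = model.shared_forward(data.drug_codes[r], data.cell_codes[k])
        scores, probs = model.sensitivity_forward(rep_I)
        for i, (d, c) in enumerate(pairs):
            sen = data.sensitivity[(d, c)]
            rows.append({
                "drug_id": d, "cell_id": c, "fold": fold,
                "y_true": sen.ri_score, "y_pred": float(scores[i]),
                "label_true": 1 if sen.label == POSITIVE else 0,
                "prob_pred": float(probs[i, 1]) if probs is not None else np.nan,
            })
    return pd.DataFrame(rows, columns=["drug_id", "cell_id", "fold", "y_true",
                                       "y_pred", "label_true", "prob_pred"])


@dataclass
class CvResult:
    synergy_predictions: pd.DataFrame
    sensitivity_predictions: pd.DataFrame
    fold_metrics: pd.DataFrame
    histories: list[list[LossBreakdown]]

    def overall(self) -> pd.DataFrame:
        """Mean and std of each metric across folds."""
        num = self.fold_metrics.drop(columns=["fold"])
        return pd.DataFrame({"mean": num.mean(), "std": num.std()})


def _fold_metric_row(fold: int, syn: pd.DataFrame, sen: pd.DataFrame) -> dict:
    row: dict = {"fold": fold}
    if len(syn):
        m = regression_metrics(syn.y_true.to_numpy(), syn.y_pred.to_numpy())
        row.update(syn_mse=m.mse, syn_rmse=m.rmse,
                   syn_pcc=np.nan if m.pcc is None else m.pcc)
        if syn.prob_pred.notna().all() and 0 < syn.label_true.sum() < len(syn):
            c = classification_metrics(syn.label_true.to_numpy(),
                                       syn.prob_pred.to_numpy())
            row.update(syn_roc_auc=c.roc_auc, syn_pr_auc=c.pr_auc, syn_acc=c.acc)
    if len(sen) >= 2:
        m = regression_metrics(sen.y_true.to_numpy(), sen.y_pred.to_numpy())
        row.update(sen_mse=m.mse, sen_rmse=m.rmse,
                   sen_pcc=np.nan if m.pcc is None else m.pcc)
        if sen.prob_pred.notna().all() and 0 < sen.label_true.sum() < len(sen):
            c = classification_metrics(sen.label_true.to_numpy(),
                                       sen.prob_pred.to_numpy())
            row.update(sen_roc_auc=c.roc_auc, sen_pr_auc=c.pr_auc, sen_acc=c.acc)
    return row


def cross_validate(data: EncodedDataset, spec: PredictorSpec,
                   opts: TrainOptions) -> CvResult:
    """Five-fold CV over combination folds with drug-fold-matched sensitivity.

    In round f the samples of combination fold f are the test set, one
    rotating training fold (seed-determined) is carved out for validation
    and early stopping, and the remaining folds train the model. Synergy is
    predicted for all test samples; sensitivity only for (drug, cell)
    pairs whose drug belongs to drug-fold f, which the leakage filter kept
    out of training.
    """
    n_folds = data.plan.n_folds
    offset = opts.seed % (n_folds - 1)
    syn_parts, sen_parts, metric_rows, histories = [], [], [], []
    for f in range(n_folds):
        val_fold = (f + 1 + offset) % n_folds
        if val_fold == f:  # pragma: no cover - offset < n_folds-1 prevents this
            val_fold = (f + 1) % n_folds
        test = [s for s in data.samples if s.combo_fold == f]
        val = [s for s in data.samples if s.combo_fold == val_fold]
        train = [s for s in data.samples
                 if s.combo_fold not in (f, val_fold)]
        fold_opts = replace(opts, held_out_drug_fold=f)
        result = train_model(data, train, val, spec, fold_opts)
        histories.append(result.history)

        syn = (_predict_synergy(result.model, data, test)
               if spec.use_synergy else pd.DataFrame())
        sen = pd.DataFrame()
        if spec.use_sensitivity:
            pairs = sorted({(s.drug_row, s.cell_id) for s in test}
                           | {(s.drug_col, s.cell_id) for s in test})
            pairs = [(d, c) for d, c in pairs
                     if data.plan.drug_folds.get(d) == f
                     and (d, c) in data.sensitivity]
            sen = _predict_sensitivity(result.model, data, pairs, f)
        syn_parts.append(syn)
        sen_parts.append(sen)
        metric_rows.append(_fold_metric_row(f, syn, sen))
    return CvResult(
        synergy_predictions=pd.concat(syn_parts, ignore_index=True)
        if any(len(p) for p in syn_parts) else pd.DataFrame(),
        sensitivity_predictions=pd.concat(sen_parts, ignore_index=True)
        if any(len(p) for p in sen_parts) else pd.DataFrame(),
        fold_metrics=pd.DataFrame(metric_rows),
        histories=histories,
    )


# ---------------------------------------------------------------------------
# variants

def spec_for_variant(variant: str, **kw) -> PredictorSpec:
    """Predictor spec for an ablation variant.

    full: both branches, all four losses. only-synergy / only-sensitivity:
    drop the other branch and its losses. regression-only: drop both
    classification heads. no-ae: built elsewhere by feeding raw features
    (the spec only changes through the code dims the caller passes).
    """
    flags = dict(use_synergy=True, use_sensitivity=True, use_classification=True)
    if variant == "only-synergy":
        flags["use_sensitivity"] = False
    elif variant == "only-sensitivity":
        flags["use_synergy"] = False
    elif variant == "regression-only":
        flags["use_classification"] = False
    elif variant not in ("full", "no-ae"):
        raise ValueError(f"unknown variant {variant!r}")
    kw = {**flags, **kw}
    return PredictorSpec(**kw)
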