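"""Evaluation metrics and threshold labelers.

Regression quality is summarized by MSE, RMSE and the Pearson correlation
coefficient; classification quality by ROC-AUC (computed through the
rank-sum statistic with ties averaged), PR-AUC (step-wise precision-recall
integration, no interpolation) and accuracy at a 0.5 probability cutoff.
Class labels use strict greater-than thresholds: a synergy score above 30
is a strong synergistic combination, a monotherapy response above 50 is a
sensitive drug-cell pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

POSITIVE = "positive"
NEGATIVE = "negative"

SYNERGY_THRESHOLD = 30.0
SENSITIVITY_THRESHOLD = 50.0


@dataclass(frozen=True)
class RegressionMetrics:
    mse: float
    rmse: float
    pcc: float | None  # None when undefined (constant truth)

    @property
    def pcc_defined(self) -> bool:
        return self.pcc is not None


@dataclass(frozen=True)
class ClassificationMetrics:
    roc_auc: float
    pr_auc: float
    acc: float


def label_synergy(score: float, threshold: float = SYNERGY_THRESHOLD) -> str:
    """Positive iff the synergy score strictly exceeds the threshold."""
    return POSITIVE if score > threshold else NEGATIVE


def label_sensitivity(score: float, threshold: float = SENSITIVITY_THRESHOLD) -> str:
    return POSITIVE if score > threshold else NEGATIVE


def regression_metrics(y: np.ndarray, y_hat: np.ndarray) -> RegressionMetrics:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    mse = float(np.mean((y - y_hat) ** 2))
    rmse = float(np.sqrt(mse))
    if np.std(y) == 0.0 or np.std(y_hat) == 0.0:
        pcc = None
    else:
        pcc = float(np.corrcoef(y, y_hat)[0, 1])
    return RegressionMetrics(mse=mse, rmse=rmse, pcc=pcc)


def roc_auc(labels: np.ndarray, probs: np.ndarray) -> float:
    """ROC-AUC via the Mann-Whitney rank statistic, ties averaged."""
    labels = np.asarray(labels).astype(bool)
    probs = np.asarray(probs, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = rankdata(probs)  # average ranks for ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(labels: np.ndarray, probs: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Sums precision x (recall increment) over thresholds taken at the sorted
    unique scores, which equals the average-precision formulation.
    """
    labels = np.asarray(labels).astype(bool)
    probs = np.asarray(probs, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC needs at least one positive")
    order = np.argsort(-probs, kind="stable")
    sorted_labels = labels[order]
    sorted_probs = probs[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # thresholds sit at the last index of each tied score block
    block_end = np.r_[sorted_probs[1:] != sorted_probs[:-1], True]
    tp, fp = tp[block_end], fp[block_end]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - recall_prev)))


def classification_metrics(labels: np.ndarray, probs: np.ndarray) -> ClassificationMetrics:
    labels = np.asarray(labels).astype(bool)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("length mismatch")
    acc = float(np.mean((probs >= 0.5) == labels))
    return ClassificationMetrics(roc_auc=roc_auc(labels, probs),
                                 pr_auc=pr_auc(labels, probs), acc=acc)


def per_group_pcc(predictions: pd.DataFrame, grouping: str,
                  y_col: str = "y_true", yhat_col: str = "y_pred",
                  min_size: int = 3) -> pd.DataFrame:
    """Within-group Pearson correlation, e.g. per cell line or per tissue.

    Groups with fewer than ``min_size`` samples (or constant truth) are
    flagged with a null pcc rather than silently dropped.
    """
    rows = []
    for group, sub in predictions.groupby(grouping, sort=True):
        n = len(sub)
        if n < min_size:
            rows.append({grouping: group, "pcc": np.nan, "n": n, "flagged": True})
            continue
        m = regression_metrics(sub[y_col].to_numpy(), sub[yhat_col].to_numpy())
        rows.append({grouping: group,
                     "pcc": np.nan if m.pcc is None else m.pcc,
                     "n": n, "flagged": m.pcc is None})
    return pd.DataFrame(rows)


def per_tissue_summary(per_cell: pd.DataFrame, cell_to_tissue: pd.Series) -> pd.DataFrame:
    """Median per-cell-line PCC within each tissue (boxplot-ready summary)."""
    df = per_cell.copy()
    df["tissue"] = df["cell_id"].map(cell_to_tissue)
    ok = df[~df["flagged"]]
    out = (ok.groupby("tissue")["pcc"]
             .agg(median_pcc="median", n_cell_lines="count")
             .reset_index())
    return out
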