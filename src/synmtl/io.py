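"""Readers and writers for the delimited-text interfaces.

All inputs are plain delimited text with headers: a drug table
(``drug_id,smiles``), an expression matrix (first column gene id, one
column per cell line, TPM values), a cell annotation table
(``cell_id,tissue``), a synergy table
(``drug_row,drug_col,cell_id,loewe_score``; replicate measurements of the
same pair on the same cell line are averaged at load time) and a
sensitivity table (``drug_id,cell_id,ri_score``). Fold plans round-trip as
two-column tables so a split can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .featurization import CellLineRecord
from .training import (CvPlan, SensitivitySample, SynergySample, pair_key)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def load_drug_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["drug_id", "smiles"], "drug table")
    df["drug_id"] = df["drug_id"].astype(str)
    return df


def load_expression(path: str | Path, already_log: bool = False) -> pd.DataFrame:
    """Genes x cells matrix, transformed to log2(TPM+1) unless already so."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError("empty expression matrix")
    if (df.to_numpy() < 0).any() and not already_log:
        raise ValueError("negative TPM values; pass already_log=True for log inputs")
    return df if already_log else np.log2(df + 1.0)


def load_cell_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "tissue"], "cell annotation table")
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def cell_records_from_tables(log_expr: pd.DataFrame,
                             annotations: pd.DataFrame) -> list[CellLineRecord]:
    tissue = dict(zip(annotations.cell_id, annotations.tissue))
    return [CellLineRecord(str(c), tissue.get(str(c), "unknown"), log_expr[c])
            for c in log_expr.columns]


def synergy_samples_from_frame(df: pd.DataFrame,
                               synergy_threshold: float = 30.0) -> list[SynergySample]:
    """Build synergy samples, averaging replicate (pair, cell) measurements."""
    _require_columns(df, ["drug_row", "drug_col", "cell_id", "loewe_score"],
                     "synergy table")
    df = df.copy()
    for c in ("drug_row", "drug_col", "cell_id"):
        df[c] = df[c].astype(str)
    key = df.apply(lambda r: pair_key(r.drug_row, r.drug_col) + (r.cell_id,), axis=1)
    grouped = df.assign(_key=key).groupby("_key", sort=True)["loewe_score"].mean()
    from .evaluation import label_synergy
    samples = []
    for (a, b, cell), score in grouped.items():
        samples.append(SynergySample(drug_row=a, drug_col=b, cell_id=cell,
                                     loewe_score=float(score),
                                     label=label_synergy(score, synergy_threshold)))
    return samples


def load_synergy_table(path: str | Path,
                       synergy_threshold: float = 30.0) -> list[SynergySample]:
    return synergy_samples_from_frame(pd.read_csv(path), synergy_threshold)


def sensitivity_samples_from_frame(df: pd.DataFrame,
                                   sensitivity_threshold: float = 50.0
                                   ) -> dict[tuple[str, str], SensitivitySample]:
    _require_columns(df, ["drug_id", "cell_id", "ri_score"], "sensitivity table")
    from .evaluation import label_sensitivity
    out: dict[tuple[str, str], SensitivitySample] = {}
    grouped = (df.assign(drug_id=df.drug_id.astype(str),
                         cell_id=df.cell_id.astype(str))
                 .groupby(["drug_id", "cell_id"], sort=True)["ri_score"].mean())
    for (d, c), score in grouped.items():
        out[(d, c)] = SensitivitySample(
            drug_id=d, cell_id=c, ri_score=float(score),
            label=label_sensitivity(score, sensitivity_threshold))
    return out


def load_sensitivity_table(path: str | Path,
                           sensitivity_threshold: float = 50.0
                           ) -> dict[tuple[str, str], SensitivitySample]:
    return sensitivity_samples_from_frame(pd.read_csv(path), sensitivity_threshold)


# ---------------------------------------------------------------------------
# fold plans

def save_fold_plan(plan: CvPlan, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"pair_key": f"{a}|{b}", "fold": f}
         for (a, b), f in sorted(plan.combo_folds.items())]
    ).to_csv(outdir / "combo_folds.csv", index=False)
    pd.DataFrame(
        [{"drug_id": d, "fold": f} for d, f in sorted(plan.drug_folds.items())]
    ).to_csv(outdir / "drug_folds.csv", index=False)


def load_fold_plan(outdir: str | Path, n_folds: int = 5) -> CvPlan:
    outdir = Path(outdir)
    combo = pd.read_csv(outdir / "combo_folds.csv")
    drug = pd.read_csv(outdir / "drug_folds.csv")
    plan = CvPlan(n_folds=n_folds)
    for r in combo.itertuples():
        a, b = r.pair_key.split("|")
        plan.combo_folds[(a, b)] = int(r.fold)
    for r in drug.itertuples():
        plan.drug_folds[str(r.drug_id)] = int(r.fold)
    return plan


# ---------------------------------------------------------------------------
# feature metadata

def save_feature_metadata(path: str | Path, *, featurizer_version: str,
                          kept_descriptor_names: list[str],
                          selected_genes: list[str],
                          drug_means: np.ndarray, drug_stds: np.ndarray,
                          cell_means: np.ndarray, cell_stds: np.ndarray) -> None:
    payload = {
        "featurizer_version": featurizer_version,
        "kept_descriptor_names": list(kept_descriptor_names),
        "selected_genes": list(selected_genes),
        "drug_zscore_means": np.asarray(drug_means).tolist(),
        "drug_zscore_stds": np.asarray(drug_stds).tolist(),
        "cell_zscore_means": np.asarray(cell_means).tolist(),
        "cell_zscore_stds": np.asarray(cell_stds).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_feature_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
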