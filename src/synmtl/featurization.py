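"""Drug and cell-line feature engineering.

Drugs are represented by a hashed circular (Morgan/ECFP-style) fingerprint
folded to a fixed number of binary bits, concatenated with the full RDKit
scalar descriptor panel after dropping descriptors with missing values or
zero variance across the drug set. Cell lines are represented by
log2(TPM+1) expression restricted to the top-k most variable genes. Both
feature blocks are z-scored per column, and the normalization statistics
are stored so unseen drugs or cell lines can be projected into the same
space.

The exact fingerprint bit mapping depends on the featurizer version, so
the RDKit version is recorded in every feature-set's metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

FEATURIZER_VERSION = f"rdkit-{rdkit.__version__}"


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be turned into features."""


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    fingerprint: np.ndarray | None = None
    descriptors: pd.Series | None = None


@dataclass
class DrugFeatureSet:
    records: list[DrugRecord]
    kept_descriptor_names: list[str]
    feature_matrix: np.ndarray  # drugs x (n_bits + kept descriptors), z-scored
    zscore_means: np.ndarray
    zscore_stds: np.ndarray
    n_bits: int
    featurizer_version: str = FEATURIZER_VERSION

    @property
    def drug_ids(self) -> list[str]:
        return [r.drug_id for r in self.records]

    def row(self, drug_id: str) -> np.ndarray:
        return self.feature_matrix[self.drug_ids.index(drug_id)]

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Project raw (unnormalized) feature rows with the stored statistics."""
        return (raw - self.zscore_means) / self.zscore_stds


@dataclass
class CellLineRecord:
    cell_id: str
    tissue: str
    expression: pd.Series  # log2(TPM+1), indexed by gene


@dataclass
class CellLineFeatureSet:
    records: list[CellLineRecord]
    selected_genes: list[str]
    feature_matrix: np.ndarray  # cells x k, z-scored
    zscore_means: np.ndarray
    zscore_stds: np.ndarray

    @property
    def cell_ids(self) -> list[str]:
        return [r.cell_id for r in self.records]

    def row(self, cell_id: str) -> np.ndarray:
        return self.feature_matrix[self.cell_ids.index(cell_id)]

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.zscore_means) / self.zscore_stds


def _mol(smiles: str, drug_id: str | None = None):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for drug {drug_id!r}" if drug_id else ""
        raise FeaturizationError(f"unparseable SMILES {smiles!r}{who}")
    return mol


def compute_fingerprint(smiles: str, radius: int = 3, n_bits: int = 1024,
                        drug_id: str | None = None) -> np.ndarray:
    """Hashed circular fingerprint, counts collapsed to 0/1 presence bits."""
    mol = _mol(smiles, drug_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.int8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def compute_descriptors(smiles: str, drug_id: str | None = None) -> pd.Series:
    """Full RDKit scalar descriptor panel; non-computable entries become NaN."""
    mol = _mol(smiles, drug_id)
    values = Descriptors.CalcMolDescriptors(mol)
    out = {}
    for name, v in values.items():
        try:
            fv = float(v)
        except (TypeError, ValueError):
            fv = math.nan
        out[name] = fv if math.isfinite(fv) else math.nan
    return pd.Series(out, dtype=float)


def filter_descriptors(panel: pd.DataFrame) -> list[str]:
    """Names of descriptors with no missing value and non-zero variance.

    Survivors keep the panel's native column order so the feature layout is
    reproducible across runs.
    """
    if len(panel) < 2:
        raise ValueError("descriptor filtering needs at least 2 drugs")
    kept = []
    for name in panel.columns:
        col = panel[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            continue
        if np.all(col == col[0]):
            continue
        kept.append(name)
    if not kept:
        raise ValueError("all descriptor columns dropped; degenerate drug set")
    return kept


def _zscore_fit(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Zero-variance columns (e.g. constant fingerprint bits) are centered but
    # not scaled: std is replaced by 1 to keep the transform defined.
    means = matrix.mean(axis=0)
    stds = matrix.std(axis=0)
    stds = np.where(stds == 0.0, 1.0, stds)
    return (matrix - means) / stds, means, stds


def featurize_drugs(table: pd.DataFrame, radius: int = 3,
                    n_bits: int = 1024) -> list[DrugRecord]:
    """Fingerprint + descriptor panel for each row of a drug_id/smiles table."""
    records = []
    for row in table.itertuples(index=False):
        rec = DrugRecord(drug_id=str(row.drug_id), smiles=row.smiles)
        rec.fingerprint = compute_fingerprint(row.smiles, radius, n_bits, rec.drug_id)
        rec.descriptors = compute_descriptors(row.smiles, rec.drug_id)
        records.append(rec)
    return records


def build_drug_features(drugs: list[DrugRecord],
                        kept_descriptor_names: list[str] | None = None) -> DrugFeatureSet:
    """Concatenate fingerprint and surviving descriptors, then z-score."""
    if not drugs:
        raise ValueError("empty drug list")
    panel = pd.DataFrame({r.drug_id: r.descriptors for r in drugs}).T
    if kept_descriptor_names is None:
        kept_descriptor_names = filter_descriptors(panel)
    if not kept_descriptor_names:
        raise ValueError("kept_descriptor_names must be non-empty")
    n_bits = len(drugs[0].fingerprint)
    fp = np.stack([r.fingerprint for r in drugs]).astype(float)
    if fp.shape[1] != n_bits:
        raise ValueError("inconsistent fingerprint widths")
    desc = panel[kept_descriptor_names].to_numpy(dtype=float)
    if np.isnan(desc).any():
        raise ValueError("kept descriptors contain missing values")
    raw = np.hstack([fp, desc])
    feats, means, stds = _zscore_fit(raw)
    return DrugFeatureSet(
        records=drugs,
        kept_descriptor_names=list(kept_descriptor_names),
        feature_matrix=feats,
        zscore_means=means,
        zscore_stds=stds,
        n_bits=n_bits,
    )


def impute_missing_genes(matrix: pd.DataFrame, target_cell: CellLineRecord) -> CellLineRecord:
    """Fill genes missing from a cell with per-gene means over reference cells.

    ``matrix`` is genes x cells (log2(TPM+1)).
    """
    reference_genes = matrix.index
    shared = reference_genes.intersection(target_cell.expression.index)
    if len(shared) == 0:
        raise ValueError(f"cell {target_cell.cell_id!r} shares no genes with the reference")
    missing = reference_genes.difference(target_cell.expression.index)
    if len(missing) == 0:
        return target_cell
    fill = matrix.loc[missing].mean(axis=1)
    expr = pd.concat([target_cell.expression, fill]).reindex(reference_genes)
    return CellLineRecord(target_cell.cell_id, target_cell.tissue, expr)


def build_cell_features(cells: list[CellLineRecord], k: int = 5000) -> CellLineFeatureSet:
    """Top-k variance gene selection followed by per-column z-scoring.

    Ties in variance are broken by stable gene-identifier order.
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cell lines")
    expr = pd.DataFrame({c.cell_id: c.expression for c in cells})  # genes x cells
    if expr.isna().any().any():
        raise ValueError("expression contains missing values; impute first")
    if len(expr) < k:
        raise ValueError(f"only {len(expr)} genes available, need k={k}")
    variances = expr.var(axis=1, ddof=1)
    ranking = pd.DataFrame({
        "variance": variances.to_numpy(),
        "gene_name": variances.index.astype(str),
    }, index=variances.index).sort_values(
        ["variance", "gene_name"], ascending=[False, True], kind="stable")
    selected = list(ranking.index[:k])
    raw = expr.loc[selected].to_numpy().T  # cells x k
    feats, means, stds = _zscore_fit(raw)
    return CellLineFeatureSet(
        records=cells,
        selected_genes=selected,
        feature_matrix=feats,
        zscore_means=means,
        zscore_stds=stds,
    )
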