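"""Seeded miniature dataset generator with planted, learnable structure.

Emits the four input tables the pipeline consumes — a drug/SMILES table, a
TPM expression matrix with tissue annotations, a combination-synergy table
and a monotherapy-sensitivity table — entirely from a seed, so every other
module is testable without any external download.

The planted signals act on low-dimensional projections of the *engineered*
features (the z-scored fingerprint/descriptor and expression vectors built
by the real featurization pipeline), not on detached latent variables:
monotherapy sensitivity is an affine function of a drug projection and a
cell projection, and combination synergy is a symmetric bilinear function
of the two drug projections and the cell projection. Gaussian noise is
added on top of both, and the synergy scale is calibrated so a target
fraction of samples exceeds the +30 strong-synergy threshold. The planted
weights and calibration constants are stored in the provenance record, so
the noiseless scores are exactly recomputable.

This generator mimics the scale and positive rate of real combination
screens, not real chemical space, expression covariance, or real synergy
score distributions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .config import derive_seed
from .featurization import (build_cell_features, build_drug_features,
                            featurize_drugs, CellLineRecord)

# Fragments that stay chemically valid under plain concatenation in a
# linear SMILES string.
_START_FRAGMENTS = ["C", "CC", "OC", "NC", "c1ccccc1", "C1CCCCC1"]
_CHAIN_FRAGMENTS = [
    "C", "CC", "CCC", "C(C)C", "CO", "CN", "C(=O)O", "C(=O)N",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "CS", "C(F)(F)F",
    "C(Cl)", "C(Br)", "C=C", "C#N",
]
_TISSUES = ["lung", "breast", "colon", "skin"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 40
    n_cells: int = 20
    n_genes: int = 2000
    k_genes: int = 1000          # top-variance genes kept by the fixture pipeline
    pair_fraction: float = 0.6
    noise_sd_synergy: float = 5.0
    noise_sd_sensitivity: float = 5.0
    positive_rate_target: float = 0.1
    replicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_cells", "n_genes", "k_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pair_fraction", "positive_rate_target"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


def generate_smiles(n: int, seed: int = 0, max_fragments: int = 5) -> list[str]:
    """Compose n distinct, parseable SMILES from a small fragment grammar."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not generate enough distinct SMILES")
        k = int(rng.integers(1, max_fragments + 1))
        smiles = rng.choice(_START_FRAGMENTS) + "".join(
            rng.choice(_CHAIN_FRAGMENTS) for _ in range(k))
        if smiles in seen:
            continue
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(smiles)
        seen.add(canonical)
        out.append(smiles)
    return out


def generate_expression(n_cells: int, n_genes: int,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal TPM draws with gene-specific spread, plus tissue labels.

    Gene means and dispersions vary so the variance ranking used by the
    feature pipeline is non-degenerate. Cells are assigned round-robin to
    a handful of synthetic tissue labels.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cells = [f"CELL{i:03d}" for i in range(n_cells)]
    mu = rng.uniform(0.0, 8.0, size=n_genes)          # mean log2 expression
    sigma = rng.uniform(0.05, 2.0, size=n_genes)      # per-gene spread
    log2_expr = rng.normal(mu[:, None], sigma[:, None], size=(n_genes, n_cells))
    tpm = np.maximum(2.0 ** log2_expr - 1.0, 0.0)
    expr = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"), columns=cells)
    ann = pd.DataFrame({"cell_id": cells,
                        "tissue": [_TISSUES[i % len(_TISSUES)] for i in range(n_cells)]})
    return expr, ann


def _unit_projection(features: np.ndarray, w: np.ndarray) -> np.ndarray:
    p = features @ w
    sd = p.std()
    return p / sd if sd > 0 else p


def plant_scores(drug_features: np.ndarray, cell_features: np.ndarray,
                 drug_ids: list[str], cell_ids: list[str],
                 config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Plant sensitivity and synergy signals on feature projections.

    Returns the synergy table, the sensitivity table, and a provenance dict
    from which the noiseless scores can be recomputed exactly.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "plant"))
    n_drugs, d_dim = drug_features.shape
    n_cells, c_dim = cell_features.shape

    w_drug = rng.normal(size=d_dim) / np.sqrt(d_dim)
    w_cell = rng.normal(size=c_dim) / np.sqrt(c_dim)
    p = _unit_projection(drug_features, w_drug)       # per-drug scalar
    q = _unit_projection(cell_features, w_cell)       # per-cell scalar

    # --- monotherapy sensitivity: affine in (p, q), centered near 50 -------
    raw_sen = p[:, None] + 0.5 * q[None, :]
    z_sen = (raw_sen - raw_sen.mean()) / raw_sen.std()
    sen_clean = 50.0 + 18.0 * z_sen
    sen_noise = rng.normal(0.0, config.noise_sd_sensitivity, size=sen_clean.shape)
    sen_rows = [
        {"drug_id": drug_ids[i], "cell_id": cell_ids[j],
         "ri_score": sen_clean[i, j] + sen_noise[i, j]}
        for i in range(n_drugs) for j in range(n_cells)
    ]
    sensitivity = pd.DataFrame(sen_rows)

    # --- combination synergy: symmetric bilinear in (p_i, p_j, q) ----------
    all_pairs = list(itertools.combinations(range(n_drugs), 2))
    n_keep = max(1, int(round(config.pair_fraction * len(all_pairs))))
    keep = rng.permutation(len(all_pairs))[:n_keep]
    pairs = [all_pairs[i] for i in sorted(keep)]

    raw = np.array([p[i] * p[j] + 0.7 * (p[i] + p[j]) * q[k]
                    for i, j in pairs for k in range(n_cells)])
    z = (raw - raw.mean()) / raw.std()
    # calibrate so ~positive_rate_target of the noiseless scores exceed +30
    cutoff = float(np.quantile(z, 1.0 - config.positive_rate_target))
    syn_scale = 20.0
    syn_shift = 30.0 - syn_scale * cutoff
    syn_clean = syn_shift + syn_scale * z

    syn_rows = []
    idx = 0
    for i, j in pairs:
        for k in range(n_cells):
            score = syn_clean[idx] + rng.normal(0.0, config.noise_sd_synergy)
            syn_rows.append({"drug_row": drug_ids[i], "drug_col": drug_ids[j],
                             "cell_id": cell_ids[k], "loewe_score": score})
            if rng.random() < config.replicate_fraction:
                rep = syn_clean[idx] + rng.normal(0.0, config.noise_sd_synergy)
                syn_rows.append({"drug_row": drug_ids[i], "drug_col": drug_ids[j],
                                 "cell_id": cell_ids[k], "loewe_score": rep})
            idx += 1
    synergy = pd.DataFrame(syn_rows)

    provenance = {
        "w_drug": w_drug.tolist(), "w_cell": w_cell.tolist(),
        "p_scale": float((drug_features @ w_drug).std()),
        "q_scale": float((cell_features @ w_cell).std()),
        "sen_mean": float(raw_sen.mean()), "sen_std": float(raw_sen.std()),
        "syn_mean": float(raw.mean()), "syn_std": float(raw.std()),
        "syn_scale": syn_scale, "syn_shift": syn_shift,
        "positive_cutoff_z": cutoff,
    }
    return synergy, sensitivity, provenance


def recompute_clean_scores(drug_features: np.ndarray, cell_features: np.ndarray,
                           drug_ids: list[str], cell_ids: list[str],
                           provenance: dict, synergy: pd.DataFrame,
                           sensitivity: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless planted scores for given tables, from stored weights only."""
    p = drug_features @ np.asarray(provenance["w_drug"])
    p = p / provenance["p_scale"]
    q = cell_features @ np.asarray(provenance["w_cell"])
    q = q / provenance["q_scale"]
    di = {d: i for i, d in enumerate(drug_ids)}
    ci = {c: i for i, c in enumerate(cell_ids)}
    syn_raw = np.array([
        p[di[r.drug_row]] * p[di[r.drug_col]]
        + 0.7 * (p[di[r.drug_row]] + p[di[r.drug_col]]) * q[ci[r.cell_id]]
        for r in synergy.itertuples()])
    syn_clean = (provenance["syn_shift"] + provenance["syn_scale"]
                 * (syn_raw - provenance["syn_mean"]) / provenance["syn_std"])
    sen_raw = np.array([p[di[r.drug_id]] + 0.5 * q[ci[r.cell_id]]
                        for r in sensitivity.itertuples()])
    sen_clean = 50.0 + 18.0 * (sen_raw - provenance["sen_mean"]) / provenance["sen_std"]
    return syn_clean, sen_clean


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    drugs: pd.DataFrame            # drug_id, smiles
    expression: pd.DataFrame       # genes x cells, TPM
    annotations: pd.DataFrame      # cell_id, tissue
    synergy: pd.DataFrame          # drug_row, drug_col, cell_id, loewe_score
    sensitivity: pd.DataFrame      # drug_id, cell_id, ri_score
    provenance: dict


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full fixture: SMILES -> engineered features -> planted score tables."""
    smiles = generate_smiles(config.n_drugs, derive_seed(config.seed, "smiles"))
    drug_ids = [f"DRUG{i:03d}" for i in range(config.n_drugs)]
    drugs = pd.DataFrame({"drug_id": drug_ids, "smiles": smiles})

    expr, ann = generate_expression(config.n_cells, config.n_genes,
                                    derive_seed(config.seed, "expression"))

    records = featurize_drugs(drugs)
    drug_fs = build_drug_features(records)
    log_expr = np.log2(expr + 1.0)
    cell_records = [
        CellLineRecord(c, t, log_expr[c])
        for c, t in zip(ann.cell_id, ann.tissue)
    ]
    cell_fs = build_cell_features(cell_records, k=config.k_genes)

    synergy, sensitivity, provenance = plant_scores(
        drug_fs.feature_matrix, cell_fs.feature_matrix,
        drug_ids, list(ann.cell_id), config)
    provenance["config"] = asdict(config)
    return SyntheticDataset(config=config, drugs=drugs, expression=expr,
                            annotations=ann, synergy=synergy,
                            sensitivity=sensitivity, provenance=provenance)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four input tables plus the provenance record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": outdir / "drugs.csv",
        "expression": outdir / "expression.csv",
        "annotations": outdir / "cell_annotations.csv",
        "synergy": outdir / "synergy.csv",
        "sensitivity": outdir / "sensitivity.csv",
        "provenance": outdir / "provenance.json",
    }
    ds.drugs.to_csv(paths["drugs"], index=False)
    ds.expression.to_csv(paths["expression"])
    ds.annotations.to_csv(paths["annotations"], index=False)
    ds.synergy.to_csv(paths["synergy"], index=False)
    ds.sensitivity.to_csv(paths["sensitivity"], index=False)
    with open(paths["provenance"], "w") as fh:
        json.dump(ds.provenance, fh, indent=1)
    return paths
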