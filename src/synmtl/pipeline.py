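"""High-level orchestration: features -> encoders -> encoded dataset.

Each stage draws its randomness from a seed derived from the single run
seed with a stable stage tag, so stages can be rerun in isolation and the
whole pipeline is reproducible from (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .autoencoder import AutoencoderSpec, TrainedAutoencoder, encode, pretrain_autoencoder
from .config import Config, derive_seed
from .featurization import (CellLineFeatureSet, DrugFeatureSet,
                            build_cell_features, build_drug_features,
                            featurize_drugs)
from .predictor import PredictorSpec
from .training import (CvPlan, EncodedDataset, SensitivitySample,
                       SynergySample, assign_combo_folds, assign_drug_folds,
                       spec_for_variant)


def build_features(drug_table: pd.DataFrame, log_expr: pd.DataFrame,
                   annotations: pd.DataFrame, cfg: Config
                   ) -> tuple[DrugFeatureSet, CellLineFeatureSet]:
    records = featurize_drugs(drug_table, radius=cfg.fp_radius, n_bits=cfg.fp_bits)
    drug_fs = build_drug_features(records)
    cells = io.cell_records_from_tables(log_expr, annotations)
    cell_fs = build_cell_features(cells, k=cfg.k_genes)
    return drug_fs, cell_fs


def pretrain_encoders(drug_fs: DrugFeatureSet, cell_fs: CellLineFeatureSet,
                      cfg: Config) -> tuple[TrainedAutoencoder, TrainedAutoencoder]:
    drug_spec = AutoencoderSpec(input_dim=drug_fs.feature_matrix.shape[1],
                                code_dim=cfg.c_drug, dropout_rate=cfg.ae_dropout,
                                seed=derive_seed(cfg.seed, "ae-drug"))
    cell_spec = AutoencoderSpec(input_dim=cell_fs.feature_matrix.shape[1],
                                code_dim=cfg.c_cell, dropout_rate=cfg.ae_dropout,
                                seed=derive_seed(cfg.seed, "ae-cell"))
    drug_ae = pretrain_autoencoder(drug_fs.feature_matrix, drug_spec,
                                   epochs=cfg.ae_epochs, batch_size=cfg.ae_batch_size,
                                   patience=cfg.ae_patience)
    cell_ae = pretrain_autoencoder(cell_fs.feature_matrix, cell_spec,
                                   epochs=cfg.ae_epochs, batch_size=cfg.ae_batch_size,
                                   patience=cfg.ae_patience)
    return drug_ae, cell_ae


def make_plan(samples: list[SynergySample], drug_ids: list[str],
              cfg: Config) -> CvPlan:
    plan = assign_combo_folds(samples, n_folds=cfg.n_folds,
                              seed=derive_seed(cfg.seed, "combo-folds"))
    assign_drug_folds(drug_ids, n_folds=cfg.n_folds,
                      seed=derive_seed(cfg.seed, "drug-folds"), plan=plan)
    return plan


def assemble(drug_fs: DrugFeatureSet, cell_fs: CellLineFeatureSet,
             samples: list[SynergySample],
             sensitivity: dict[tuple[str, str], SensitivitySample],
             plan: CvPlan, cfg: Config,
             drug_ae: TrainedAutoencoder | None = None,
             cell_ae: TrainedAutoencoder | None = None) -> EncodedDataset:
    """Encode features (or pass them raw for the no-AE variant) and bundle."""
    if cfg.variant == "no-ae" or drug_ae is None or cell_ae is None:
        drug_codes = drug_fs.feature_matrix
        cell_codes = cell_fs.feature_matrix
    else:
        drug_codes = encode(drug_ae, drug_fs.feature_matrix)
        cell_codes = encode(cell_ae, cell_fs.feature_matrix)
    for s in samples:
        if s.combo_fold < 0:
            s.combo_fold = plan.combo_folds[
                tuple(sorted((s.drug_row, s.drug_col)))]
    for sen in sensitivity.values():
        sen.drug_fold = plan.drug_folds.get(sen.drug_id, -1)
    return EncodedDataset(drug_codes=np.asarray(drug_codes, dtype=float),
                          cell_codes=np.asarray(cell_codes, dtype=float),
                          drug_ids=drug_fs.drug_ids, cell_ids=cell_fs.cell_ids,
                          samples=samples, sensitivity=sensitivity, plan=plan)


def predictor_spec(cfg: Config, data: EncodedDataset,
                   shared_first: int | None = None,
                   learning_rate: float | None = None) -> PredictorSpec:
    first = shared_first if shared_first is not None else cfg.shared_first_layer
    return spec_for_variant(
        cfg.variant,
        drug_code_dim=data.drug_codes.shape[1],
        cell_code_dim=data.cell_codes.shape[1],
        shared_layer_sizes=(first, max(1, first // 2)),
        dropout_rate=cfg.dropout,
        learning_rate=learning_rate if learning_rate is not None else cfg.learning_rate,
        seed=derive_seed(cfg.seed, "predictor"),
    )


@dataclass
class PreparedRun:
    drug_fs: DrugFeatureSet
    cell_fs: CellLineFeatureSet
    drug_ae: TrainedAutoencoder | None
    cell_ae: TrainedAutoencoder | None
    data: EncodedDataset
    plan: CvPlan


def prepare_from_tables(drug_table: pd.DataFrame, log_expr: pd.DataFrame,
                        annotations: pd.DataFrame,
                        samples: list[SynergySample],
                        sensitivity: dict[tuple[str, str], SensitivitySample],
                        cfg: Config) -> PreparedRun:
    """The full preprocessing pipeline from loaded tables to trainable data."""
    drug_fs, cell_fs = build_features(drug_table, log_expr, annotations, cfg)
    drug_ae = cell_ae = None
    if cfg.variant != "no-ae":
        drug_ae, cell_ae = pretrain_encoders(drug_fs, cell_fs, cfg)
    plan = make_plan(samples, drug_fs.drug_ids, cfg)
    data = assemble(drug_fs, cell_fs, samples, sensitivity, plan, cfg,
                    drug_ae, cell_ae)
    return PreparedRun(drug_fs, cell_fs, drug_ae, cell_ae, data, plan)
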