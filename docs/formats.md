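# File formats

All interfaces are UTF-8 delimited text with headers.

## Inputs

| file | columns | notes |
| --- | --- | --- |
| `drugs.csv` | `drug_id,smiles` | one row per drug |
| `expression.csv` | first column gene id, one column per cell line | values are TPM; the loader applies log2(TPM+1) unless `expression_is_log: true` |
| `cell_annotations.csv` | `cell_id,tissue` | |
| `synergy.csv` | `drug_row,drug_col,cell_id,loewe_score` | replicate rows for the same unordered pair and cell line are averaged at load |
| `sensitivity.csv` | `drug_id,cell_id,ri_score` | RI monotherapy sensitivity |

## Fold plans (exported by `train` / `cv`, importable for exact replay)

| file | columns |
| --- | --- |
| `combo_folds.csv` | `pair_key,fold` — pair key is the sorted pair joined with `|` |
| `drug_folds.csv` | `drug_id,fold` |

## Outputs

* `drug_features.csv` / `cell_features.csv` — z-scored feature matrices,
  row index = entity id.
* `feature_metadata.json` — featurizer version, kept descriptor names,
  selected genes, z-score means/stds.
* `synergy_predictions.csv` — `drug_row,drug_col,cell_id,fold,y_true,
  y_pred,label_true,prob_pred` (out-of-fold, order-averaged).
* `sensitivity_predictions.csv` — same shape keyed by `drug_id,cell_id`.
* `fold_metrics.csv` / `overall_metrics.csv` — MSE, RMSE, PCC, ROC-AUC,
  PR-AUC, ACC per fold and mean ± sd.
* `per_cell_line_pcc.csv` / `per_tissue_summary.csv` — grouped
  correlations (groups with < 3 samples flagged) and per-tissue medians.
* `history.csv` — per-epoch validation loss breakdown.
* Model checkpoints — a `.npz` parameter container plus a JSON sidecar
  (spec fields, seed, featurizer version).
* `run_manifest.json` — config snapshot, seed, software versions, input
  file SHA-256 digests, timestamp. Every output directory contains one.
* `provenance.json` (from `simulate`) — generator parameters, planted
  projection weights and calibration constants; the noiseless planted
  scores are exactly recomputable from it.
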