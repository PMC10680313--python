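# Methods

## Problem and model

`synmtl` predicts, for a pair of anticancer drugs and a cancer cell line,
(i) the combination's Loewe-additivity synergy score together with the
probability that the combination is strongly synergistic, and (ii) each
drug's monotherapy sensitivity on that cell line (the RI score — the
normalized, log10-transformed area under the single-drug dose–response
curve) with the probability that the drug–cell pair is sensitive. The two
tasks are learned jointly: they share a trunk network, so monotherapy
response data act as an auxiliary signal for the harder combination task.

### Input representations

* **Drugs.** A hashed circular (Morgan/ECFP-style) fingerprint with radius
  3, folded to 1024 binary presence bits, concatenated with the full RDKit
  scalar descriptor panel after dropping any descriptor that has a missing
  value or zero variance across the drug set. Surviving descriptors keep
  the panel's native order, and the kept-name list is persisted so feature
  layout is reproducible. The final width is therefore dataset-dependent
  (1024 + number of survivors). Columns are z-scored; the fitted means and
  standard deviations are stored and reapplied to unseen drugs. Constant
  columns (possible among fingerprint bits) are centered and divided by 1
  rather than 0. Fingerprint bit mappings depend on the featurizer
  version, so the RDKit version is recorded in all metadata and the test
  fixture bits are frozen rather than recomputed.
* **Cell lines.** TPM expression is transformed to log2(TPM+1); genes
  missing from a cell line can be imputed with per-gene means over the
  reference panel. The k = 5000 genes with the largest variance across
  cell lines are kept (ties broken by stable gene-identifier order), then
  z-scored with stored statistics.
* Z-score statistics are fitted once on the full feature matrix before any
  split. A `zscore_scope: train-only` config mode exists for users who
  prefer strictly split-safe normalization; the default mirrors the
  preprocessing-first pipeline and shares no label information, only
  feature marginals.

### Autoencoders

Each feature block is compressed by a pre-trained autoencoder: two fully
connected encoder layers (ReLU between them, dropout rate 0.2 after the
encoder activation) down to a code of width 128 (drugs) or 256 (cell
lines), and a mirrored two-layer decoder. The training objective is the
mean over samples of the summed squared reconstruction error,
`L(x, x̂) = Σᵢ‖xᵢ − x̂ᵢ‖² / n`. The hidden width defaults to the geometric
mean of input and code widths rounded to a power of two; optimizer is
Adam, batch 64, with early stopping on a held-out 10% reconstruction
loss. After pre-training the encoder is frozen and used for input
transformation only (a fine-tune path is deliberately not provided; the
`no-ae` variant bypasses the encoders entirely and feeds raw features to
the predictor).

### Predictor

The shared module takes the concatenated drug and cell codes through two
FC layers, each with batch normalization and ReLU. Applied to
(drug_row, cell) and (drug_col, cell) it yields representations I and II.
The synergy branch consumes I‖II through FC layers with ReLU and dropout
(default rate 0.5; widths s, s/2, s/4 where s is the shared output
width), ending in a linear regression head and a 2-unit softmax
classification head. The sensitivity branch has the same shape but
consumes I alone, which makes a drug's predicted monotherapy response
independent of its combination partner by construction. Batch
normalization is used only in the shared module.

Because concatenation is order-sensitive, every training sample enters in
both drug orders, and pair-level predictions average the (A,B) and (B,A)
outputs — the reported synergy score and probability are therefore exactly
symmetric in the drugs. Sensitivity is predicted for the row-position drug
of each ordering.

### Losses and training

The objective is the unweighted sum of four terms
(`mse_syn + mse_sen + bce_syn + bce_sen`): mean squared error for the two
regression heads and binary cross entropy (probabilities clamped to
[1e-7, 1−1e-7]) for the two softmax heads. The MSE terms are on score
scales (hundreds) and the BCE terms are order 1; per-term weights are
exposed through variant flags but default to 1 to keep the objective
faithful. Training runs mini-batch Adam (default batch 128). Early
stopping monitors the total validation loss with patience 100 epochs and
a 500-epoch cap by default, and the checkpoint with the lowest validation
loss is kept and used for test prediction (no refit on train+validation).

### Dual fold plans and the leakage filter

Generalization is assessed with two independent five-fold partitions:

* **combination folds** — unordered drug pairs are shuffled and dealt
  round-robin, so each pair lives in exactly one fold and fold sizes
  differ by at most one pair;
* **drug folds** — the same construction at drug granularity, used only by
  the sensitivity task.

In CV round f, fold f is the synergy test set; one rotating
seed-determined training fold is carved out as the validation set, and
the rest train the model. Within every mini-batch, sensitivity rows whose
row-drug belongs to drug-fold f are removed before the sensitivity losses
are computed (an empty surviving sub-batch contributes exactly zero, with
no renormalization of the other terms); the synergy sub-batch is never
filtered. At test time the roles flip: sensitivity is predicted only for
(drug, cell) pairs whose drug belongs to drug-fold f. Each duplicated
ordering contributes its own row-drug sensitivity term, subject to the
same filter. Grid search covers first-layer size {2048, 4096, 8192} ×
learning rate {5e-4, 1e-4, 5e-5} by default; ties prefer the lower
learning rate, then the smaller layer.

### Classification thresholds and metrics

Labels use strict greater-than thresholds: synergy score > 30 is a strong
synergistic combination; RI > 50 is a sensitive pair (the 50 boundary's
side is not standardized anywhere; strict is used for consistency).
Regression quality is MSE / RMSE / Pearson correlation (constant-truth
groups are flagged, never silently NaN); classification quality is
ROC-AUC via the rank-sum statistic with averaged ties, PR-AUC by
step-wise (non-interpolated) precision–recall integration, and accuracy
at a 0.5 probability cutoff. Per-cell-line correlations (groups under 3
samples flagged) and per-tissue medians support tissue-level reporting.

## Numerical implementation

The networks are implemented directly on NumPy (dense layers with
He-normal init, inverted dropout, batch normalization with running
statistics, softmax heads, Adam, explicit backpropagation). All
randomness — fold shuffles, weight init, dropout masks, batch order —
derives from a single run seed fanned out per stage through a stable
hash, so runs are bit-reproducible on a fixed BLAS and any stage can be
rerun in isolation. Inference disables dropout and uses running
batch-norm statistics, making predictions batch-size independent.

## Synthetic data generator

The generator emulates a miniature combination screen end to end: SMILES
composed from a small chemically safe fragment grammar (all outputs
parse), a log-normal TPM matrix with gene-specific means and dispersions
(so variance ranking is meaningful) and round-robin tissue labels, and
score tables with planted signal. The planted functions act on random
low-dimensional projections of the *engineered* features — monotherapy
sensitivity is affine in a drug and a cell projection, centered near 50
with spread 18; synergy is a symmetric bilinear form of the two drug
projections and the cell projection, affinely calibrated so that a target
fraction (default 10%, matching the positive-class scarcity of large
published screens) of noiseless scores exceeds the +30 threshold.
Gaussian noise (default sd 5 on both tasks) is added on top. Planting on
real engineered features is deliberate: a bug anywhere in the feature
pipeline breaks signal recovery. Defaults are 40 drugs × 20 cell lines,
2000 genes, 60% of possible pairs (9360 synergy samples after order-free
deduplication).

What the fixture does **not** emulate: real chemical space, expression
covariance between genes, dose–response mechanics, or the heavy-tailed
empirical distribution of Loewe scores. Passing recovery tests therefore
demonstrates that the pipeline and the optimization are correct and that
the model can extract a planted signal of realistic scale — not that
published benchmark numbers on real screens are reproduced.

## Problem sizes used by tests and the acceptance script

Published-scale settings (trunk widths 2048–8192, 5000 genes, 500-epoch
cap) are the config defaults, but all shipped tests and the acceptance
script run a compact instantiation chosen as this package's desk-scale
study condition: shared trunk (256, 128), learning rate 1e-3, batch 256,
epoch cap 60 with patience 10, autoencoders 150 epochs, and the top 1000
of the fixture's 2000 genes. On this setup the five-fold out-of-fold
synergy correlation is ≈0.94 and the sensitivity correlation ≈0.9 (both
computed by `scripts/acceptance.py`, nothing hard-coded).

## Known limitations

* Single-task and multi-task variants are statistically tied on the
  synthetic fixture: the planted synergy signal is abundant and high-SNR,
  so the auxiliary sensitivity loss has no headroom to help, unlike real
  screens where synergy labels are scarce and noisy.
* CPU-only; no GPU path. Published-scale grids are expensive on one core.
* Bit-level reproducibility holds for a fixed NumPy/BLAS build; across
  BLAS implementations results agree only to floating-point tolerance.
* The descriptor panel width (and hence drug feature width) follows the
  installed RDKit version; downstream artifacts record that version.
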