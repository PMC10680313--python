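# Desk-scale training settings for the default 40-drug x 20-cell-line
# synthetic screen: compact trunk, short epoch cap. About 4 minutes for a
# full five-fold cross-validation on one CPU core.
k_genes: 1000
ae_epochs: 150
ae_patience: 20
shared_first_layer: 256
max_epochs: 60
patience: 10
batch_size: 256
learning_rate: 0.001
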