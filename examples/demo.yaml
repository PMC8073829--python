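# Small end-to-end demonstration: simulate -> preprocess -> segment ->
# featurize -> train -> cross-validate.  Run with:
#   pcg run --config examples/demo.yaml --out results/demo
seed: 1
model: lknet
n_records: 30
folds: 3
simulate:
  duration_range: [5, 12]
  murmur_snr_db: 20.0
segmentation:
  mode: sliding
  stride: 1.0
  window: 2.0
net:
  n_blocks: 4
  base_channels: 8
  kernel_size: 9
train:
  epochs: 10
  batch_size: 32
  learning_rate: 0.003
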