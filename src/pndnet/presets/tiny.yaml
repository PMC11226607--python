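# Desk-scale preset: the trainable tiny backbone on 64x64 images.
# Runs in seconds on one CPU; used by the CLI examples and tests.
backbone: tiny
image_size: 64
upsample_size: 16
region_grid: 4
pyramid_levels: [2, 3]
pool_mode: average
use_spp: true
gcn_layers: 2
gcn_features: null
use_gcn: true
dropout_rate: 0.3
head_norm: layer
preprocessing: caffe_scaled
learning_rate: 0.005
momentum: 0.9
lr_drop_factor: 5
lr_drop_epoch: 100
epochs: 30
batch_size: 12
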