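# Alternate published hyper-parameter set: learning rate 0.007, batch 8
# (the hyper-parameter table variant of the reference protocol).
backbone: resnet50
image_size: 224
upsample_size: 16
region_grid: 4
pyramid_levels: [2, 3]
pool_mode: average
use_spp: true
gcn_layers: 2
gcn_features: 2048
use_gcn: true
dropout_rate: 0.3
head_norm: layer
preprocessing: caffe
learning_rate: 0.007
momentum: 0.0
lr_drop_factor: 5
lr_drop_epoch: 100
epochs: 150
batch_size: 8
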