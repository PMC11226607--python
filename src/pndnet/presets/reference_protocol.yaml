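# Reference training protocol: ImageNet backbone, 224x224 crops from
# 256x256 inputs, SGD at 1e-3 for 150 epochs with the rate divided by 5
# after epoch 100, batch 12, dropout 0.3, 4x4 region grid with a (2, 3)
# pyramid (13 graph nodes), two 2048-wide graph convolution layers.
# Running this preset requires pretrained backbone weights, which this
# installation cannot download.
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
learning_rate: 0.001
momentum: 0.0
lr_drop_factor: 5
lr_drop_epoch: 100
epochs: 150
batch_size: 12
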