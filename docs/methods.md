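# Methods

## Model

The classifier refines CNN features with a graph stage before the softmax
head. Stages, in order, with shapes for the default tiny configuration
(64×64 input):

1. **Backbone** — final convolutional feature map, h×w×C
   (tiny: 4×4×32; the ImageNet architectures produce 7×7×2048 at 224×224,
   Inception-V3 5×5×2048 due to its unpadded stem).
2. **Bilinear upsampling** to H×W (default 16×16), half-pixel-center
   convention, no corner alignment; reduces to the identity when the
   target equals the source.
3. **Region pooling** — the map is cut into g×g (default 4×4, ω = 16)
   non-overlapping tiles, each averaged into one C-vector, row-major
   order.
4. **Spatial pyramid pooling** — the g×g grid of region descriptors is
   adaptively pooled at bin resolutions i×i and j×j (default (2, 3));
   bin b over size S spans [⌊bS/n⌋, ⌈(b+1)S/n⌉). The i²+j² = 13 pooled
   vectors, level i first and bins row-major, are the graph nodes. The
   pyramid is applied across regions (not within each region) so that the
   bins summarize inter-region context at several scales. Average pooling
   is the default (it propagates constants exactly, which the tests
   exploit); max pooling is available.
5. **Graph convolution** — the nodes form a complete graph; with
   self-loops, Â = D̃^(−1/2)(A+I)D̃^(−1/2) = J/P exactly. Two layers of
   G ← ReLU(Â G W + b), channel width kept at the backbone width
   (configurable to 1024/2048 for the large backbones; 1 or 2 layers, or
   disabled entirely, as ablation axes). Â is fixed, not learned; a path
   topology exists for testing only. Weights are Glorot-uniform, biases
   zero; no dropout between graph layers.
6. **Head** — global average pooling over the node axis, layer
   normalization (batch normalization selectable), dropout 0.3, dense
   softmax. The dense classifier is zero-initialized, so the initial loss
   is exactly ln Y and early gradients shape the head before perturbing
   the feature extractor; with random head initialization the toy-scale
   model sometimes collapsed to the uniform prediction under layer
   normalization before learning the features.

Node-order symmetry: because Â = J/P and the head pools nodes by
averaging, permuting the node rows cannot change the logits — a property
test, and a useful invariant given that the node ordering is a convention.

## Training protocol

SGD on categorical cross-entropy (probability floor 1e-12, mean over the
batch), no early stopping. The reference protocol is learning rate 1e-3,
batch 12, 150 epochs with the rate divided by 5 after epoch 100; a
published alternate preset uses rate 0.007 and batch 8. Both ship as
preset files. When a validation fraction is configured, the
best-validation-top-1 weights are restored after training.

For the trainable tiny backbone the package defaults to learning rate
5e-3 with momentum 0.9 and ≤ 50 epochs: the reference schedule targets
fine-tuning of pretrained ImageNet backbones, whereas the tiny CNN trains
from scratch on toy fixtures and needs a correspondingly larger step.

## Data handling

* **Preprocessing** follows the caffe-style convention: RGB→BGR, then
  per-channel zero-centering with the ImageNet means
  (103.939, 116.779, 123.68 in BGR order), no scaling. The estimator's
  default mode additionally divides by 255 (`caffe_scaled`) purely for
  numerical conditioning of the from-scratch tiny backbone; the exact
  convention is used verbatim with `preprocessing="caffe"`.
* **Augmentation** (off by default in the estimator, on in the reference
  presets): random rotation (±20°), scale (±0.20), translation (±0.20),
  horizontal flip, additive Gaussian noise, optional Gaussian blur, then
  a random crop to 224 (or the configured size). The magnitudes 25°/0.25
  appear in parts of the protocol description; the hyper-parameter-table
  values are the defaults and both are configurable.
* **Splitting** is stratified 70:30 per class with round(0.3·n) test
  images per class (the protocol description says only "random"; at small
  per-class counts unstratified splits are unstable, so stratification is
  the package's choice). Five-fold plans deal each class into five nearly
  equal validation chunks and assign per-class remainders to the
  currently smallest folds, so fold totals are as equal as possible: a
  2,010-image pool gives exactly 402 validation / 1,608 training images
  per fold. The test set is fixed across folds; plans serialize to JSON
  with their seed so runs replay exactly.

## Synthetic fixtures

The generator emulates class-per-folder leaf datasets at toy scale: a
textured brownish background, a leaf ellipse with a class-specific base
hue from an evenly spaced hue wheel, 1–4 class-specific lesion blobs in a
complementary color, and additive Gaussian pixel noise (default sd 8
intensity units). Classes are linearly separable from mean color alone by
construction, so small-model overfit tests measure optimization and
plumbing, not representational difficulty. Consequently, passing fixture
tests demonstrates that the pipeline trains, evaluates and explains
correctly — not that the architecture separates real deficiency symptoms,
which requires the public datasets and pretrained backbones. Identical
spec and seed reproduce bit-identical PNGs.

## Backbone accounting

The four reference architectures are declared as layer-shape tables and
counted exactly, following their Keras Applications layouts with
ImageNet-1000 heads and the total-parameter convention (batch-norm moving
statistics included; conv biases present only in ResNet-50; Inception-V3
batch norms carry no scale term). Totals: Xception 22,910,480; ResNet-50
25,636,712; Inception-V3 23,851,784; MobileNet-V2 3,538,984 — i.e. 22.9,
25.6, 23.9 and 3.5 million at one decimal. Their pretrained weights are
not downloadable in this installation, so these adapters expose geometry
and counts only and refuse to run with random weights; all runnable paths
use the tiny backbone. Published totals for the full assembled
large-backbone models are not reconstructable from the stated layer sizes
and are not modeled.

## Numerical choices

* Explicit backprop per layer, float64 throughout; gradients validated
  against central finite differences (1e-6 tolerance) end to end.
* Adaptive-pool bin boundaries use the floor/ceil rule above; ties in
  top-k ranking break toward the lower class index (documented,
  deterministic).
* Metrics: one-vs-rest TP/FP/FN per class; zero denominators define the
  metric as 0; aggregate precision/recall/F1 are unweighted (macro) means
  (the published tables do not state macro vs weighted; macro is the
  package's choice).
* Grad-CAM: channel weights are the spatial means of the target-logit
  gradient at the last convolutional stage; the weighted, ReLU-rectified
  map is bilinearly resized to the input size and then min-max
  normalized, so the maximum is exactly 1 unless the map is constant
  (then all zeros).
* t-SNE export uses PCA initialization and a perplexity capped at n/4,
  seed-controlled.
* Divergence (non-finite loss) aborts training with a diagnostic rather
  than returning garbage.

## Problem sizes in tests and the acceptance script

Fixture runs use 3 classes × 20 images at 64×64 with the tiny backbone
(13 graph nodes, ~21k parameters); training runs are ≤ 50 epochs. These
sizes exercise every stage of the method while keeping the full suite in
the low minutes on one CPU.

## Known limitations

* No runnable pretrained backbones, hence no transfer-learning results;
  the published dataset accuracies are documented but not reproduced.
* The augmentation pipeline interpolates with order-1 splines and
  reflective boundaries; it is not a pixel-exact match of any particular
  framework's augmentation ops.
* Batch-norm head statistics are running averages with momentum 0.9;
  very short trainings evaluate with barely-moved statistics.
* The numpy engine is single-threaded except for BLAS matmuls; it is
  built for correctness and testability, not throughput.
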