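"""Assembly of the full classifier and its training loop.

Pipeline: preprocessed image batch -> backbone feature map -> bilinear
upsampling -> fixed-grid region pooling -> spatial pyramid pooling into P
graph nodes -> two symmetric-normalized graph convolution layers -> global
average pooling over the node axis -> head normalization -> dropout ->
dense softmax over the classes. Ablation switches bypass the pyramid
(nodes = raw region descriptors) or the graph module entirely.

Training is plain SGD on categorical cross-entropy with a step learning
rate schedule (rate divided by ``lr_drop_factor`` after ``lr_drop_epoch``
epochs) and no early stopping; the best-validation weights are snapshotted
when a validation set is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbones import BACKBONE_REGISTRY, load_backbone
from .graph import build_adjacency
from .nn import (SGD, AvgPool2d, BatchNorm1d, BilinearUpsample, Dense, Dropout,
                 Layer, LayerNorm, glorot_uniform, softmax, softmax_cross_entropy)
from .regions import RegionConfig

__all__ = ["ModelConfig", "TrainConfig", "PNDNetModel", "assemble",
           "cross_entropy_loss", "one_hot", "train"]


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny"
    pretrained: bool = False
    image_size: int = 64
    region: RegionConfig = field(default_factory=RegionConfig)
    gcn_layers: int = 2
    gcn_features: int | None = None      # None => backbone channel width
    use_gcn: bool = True
    num_classes: int = 3
    dropout_rate: float = 0.3
    head_norm: str = "layer"
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.head_norm not in ("layer", "batch", "none"):
            raise ValueError(f"head_norm must be layer/batch/none, got {self.head_norm!r}")
        if self.use_gcn and self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1 when the GCN is enabled")
        if self.backbone not in BACKBONE_REGISTRY:
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass(frozen=True)
class TrainConfig:
    """SGD training protocol. Defaults follow the reference protocol
    (learning rate 1e-3, batch 12, 150 epochs, rate divided by 5 after
    epoch 100); the alternate published preset (rate 0.007, batch 8) ships
    in the CLI preset files."""

    learning_rate: float = 1e-3
    momentum: float = 0.0
    lr_drop_factor: float = 5.0
    lr_drop_epoch: int = 100
    epochs: int = 150
    batch_size: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_drop_factor < 1:
            raise ValueError("lr_drop_factor must be >= 1")


class _PyramidPool(Layer):
    """Batched adaptive pyramid pooling (N, g, g, C) -> (N, P, C)."""

    def __init__(self, cfg: RegionConfig):
        from .nn import adaptive_bins
        self.cfg = cfg
        g = cfg.grid
        if cfg.pool_mode == "average":
            rows = []
            for n in cfg.pyramid_levels:
                spans = adaptive_bins(n, g)
                for r0, r1 in spans:
                    for c0, c1 in spans:
                        m = np.zeros((g, g))
                        m[r0:r1, c0:c1] = 1.0 / ((r1 - r0) * (c1 - c0))
                        rows.append(m.reshape(-1))
            self.M = np.stack(rows)          # (P, g*g)
        else:
            self.bins = []
            for n in cfg.pyramid_levels:
                spans = adaptive_bins(n, g)
                for r0, r1 in spans:
                    for c0, c1 in spans:
                        self.bins.append((r0, r1, c0, c1))

    def forward(self, x, train=False):
        n, g, _, c = x.shape
        flat = x.reshape(n, g * g, c)
        if self.cfg.pool_mode == "average":
            self._in_shape = x.shape
            return np.einsum("pg,ngc->npc", self.M, flat, optimize=True)
        self._x = x
        out = np.empty((n, len(self.bins), c))
        self._argmax = []
        for bi, (r0, r1, c0, c1) in enumerate(self.bins):
            tile = x[:, r0:r1, c0:c1, :].reshape(n, -1, c)
            am = tile.argmax(axis=1)
            self._argmax.append(am)
            out[:, bi, :] = np.take_along_axis(tile, am[:, None, :], axis=1)[:, 0, :]
        return out

    def backward(self, grad):
        if self.cfg.pool_mode == "average":
            n, g, _, c = self._in_shape
            flat = np.einsum("pg,npc->ngc", self.M, grad, optimize=True)
            return flat.reshape(n, g, g, c)
        x = self._x
        n, g, _, c = x.shape
        dx = np.zeros_like(x)
        for bi, (r0, r1, c0, c1) in enumerate(self.bins):
            th, tw = r1 - r0, c1 - c0
            dtile = np.zeros((n, th * tw, c))
            np.put_along_axis(dtile, self._argmax[bi][:, None, :],
                              grad[:, bi, :][:, None, :], axis=1)
            dx[:, r0:r1, c0:c1, :] += dtile.reshape(n, th, tw, c)
        return dx


class _FlattenRegions(Layer):
    """(N, g, g, C) -> (N, g*g, C) row-major; the no-pyramid ablation path."""

    def forward(self, x, train=False):
        self._shape = x.shape
        n, g, _, c = x.shape
        return x.reshape(n, g * g, c)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _GCNLayer(Layer):
    """Batched graph convolution ReLU(A_hat X W + b) with a fixed operator."""

    def __init__(self, A_hat: np.ndarray, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.A_hat = A_hat
        self.W = glorot_uniform(rng, c_in, c_out, (c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        self._ax = np.einsum("pq,nqc->npc", self.A_hat, x, optimize=True)
        pre = self._ax @ self.W + self.b
        self._mask = pre > 0
        return pre * self._mask

    def backward(self, grad):
        grad = grad * self._mask
        self.dW += np.einsum("npc,npf->cf", self._ax, grad, optimize=True)
        self.db += grad.sum(axis=(0, 1))
        dax = grad @ self.W.T
        return np.einsum("pq,nqc->npc", self.A_hat.T, dax, optimize=True)


class _NodeGAP(Layer):
    """Global average pooling over the node axis: (N, P, C) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, grad):
        n, p, c = self._shape
        return np.broadcast_to(grad[:, None, :] / p, (n, p, c)).copy()


class PNDNetModel:
    """The assembled trainable classifier (numpy forward/backward)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = load_backbone(cfg.backbone, pretrained=cfg.pretrained, rng=rng)
        C = self.backbone.output_channels
        region = cfg.region
        grid_side = BACKBONE_REGISTRY[cfg.backbone].output_grid(cfg.image_size)
        if region.upsample_size < grid_side:
            raise ValueError(
                f"upsample_size {region.upsample_size} smaller than backbone grid {grid_side}")
        head: list[Layer] = [
            BilinearUpsample((grid_side, grid_side),
                             (region.upsample_size, region.upsample_size)),
            AvgPool2d(region.upsample_size // region.grid),
        ]
        head.append(_PyramidPool(region) if region.use_spp else _FlattenRegions())
        P = region.n_nodes
        self.adjacency = build_adjacency(P, "complete")
        width = C
        if cfg.use_gcn:
            out_width = cfg.gcn_features or C
            for l in range(cfg.gcn_layers):
                head.append(_GCNLayer(self.adjacency.A_hat, width, out_width, rng=rng))
                width = out_width
        head.append(_NodeGAP())
        if cfg.head_norm == "layer":
            head.append(LayerNorm(width))
        elif cfg.head_norm == "batch":
            head.append(BatchNorm1d(width))
        head.append(Dropout(cfg.dropout_rate, rng=np.random.default_rng(cfg.seed + 1)))
        classifier = Dense(width, cfg.num_classes, rng=rng)
        # zero-initialized classifier: the initial loss is exactly ln Y and
        # early gradients flow into the head before perturbing the features
        classifier.W[...] = 0.0
        head.append(classifier)
        self.head = head
        self.n_nodes = P
        self.feature_width = width
        # set by forward/backward: backbone map and its gradient (Grad-CAM)
        self.feature_map_: np.ndarray | None = None
        self.feature_map_grad_: np.ndarray | None = None
        self.penultimate_: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected NHWC image batch, got shape {x.shape}")
        fm = self.backbone.forward(x, train=train)
        self.feature_map_ = fm
        h = fm
        for li, layer in enumerate(self.head):
            h = layer.forward(h, train=train)
            if isinstance(layer, Dropout):
                self.penultimate_ = h if not train else None
        return h

    def backward(self, dlogits: np.ndarray, into_backbone: bool = True) -> np.ndarray:
        grad = dlogits
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        self.feature_map_grad_ = grad
        if into_backbone:
            grad = self.backbone.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.vstack(out)

    # -- parameter plumbing -------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return [self.backbone, *self.head]

    def n_parameters(self) -> int:
        return sum(int(p.size) for layer in self.layers
                   for _, p, _ in layer.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for _, p, _ in layer.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for _, p, _ in layer.parameters()]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match model parameters")
        for dst, src in zip(flat, weights):
            dst[...] = src


def assemble(cfg: ModelConfig) -> PNDNetModel:
    return PNDNetModel(cfg)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy_loss(truth_onehot: np.ndarray, probs: np.ndarray,
                       floor: float = 1e-12) -> float:
    """Mean categorical cross-entropy -sum_i Y_i log Yhat_i over the batch,
    with predicted probabilities floored at 1e-12."""
    truth_onehot = np.asarray(truth_onehot, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if truth_onehot.shape != probs.shape:
        raise ValueError(f"shape mismatch {truth_onehot.shape} vs {probs.shape}")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6) or np.any(probs < -1e-12):
        raise ValueError("probability rows must be valid distributions")
    return float(-np.sum(truth_onehot * np.log(np.clip(probs, floor, 1.0)))
                 / probs.shape[0])


def _epoch_lr(tc: TrainConfig, epoch: int) -> float:
    """Epochs are 1-based; the rate drops from epoch lr_drop_epoch + 1 on."""
    return tc.learning_rate / (tc.lr_drop_factor if epoch > tc.lr_drop_epoch else 1.0)


def train(model: PNDNetModel, X_train: np.ndarray, y_train: np.ndarray,
          tc: TrainConfig, X_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None, verbose: bool = False,
          restore_best: bool = True) -> list[dict]:
    """SGD training; returns per-epoch history rows
    (epoch, lr, train_loss, train_top1[, val_loss, val_top1])."""
    if tc.epochs and len(X_train) == 0:
        raise ValueError("training set is empty")
    Y = model.cfg.num_classes
    onehot_train = one_hot(y_train, Y)
    rng = np.random.default_rng(tc.seed)
    optimizer = SGD(model.layers, lr=tc.learning_rate, momentum=tc.momentum)
    history: list[dict] = []
    best_val, best_weights = -np.inf, None
    for epoch in range(1, tc.epochs + 1):
        optimizer.lr = _epoch_lr(tc, epoch)
        order = rng.permutation(len(X_train))
        losses = []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            logits = model.forward(X_train[idx], train=True)
            loss, _, dlogits = softmax_cross_entropy(logits, onehot_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={optimizer.lr}); lower the learning rate")
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        probs = model.predict_proba(X_train)
        top1 = float(np.mean(probs.argmax(axis=1) == y_train))
        row = {"epoch": epoch, "lr": optimizer.lr,
               "train_loss": float(np.mean(losses)), "train_top1": top1}
        if X_val is not None and len(X_val):
            vprobs = model.predict_proba(X_val)
            row["val_loss"] = cross_entropy_loss(one_hot(y_val, Y), vprobs)
            row["val_top1"] = float(np.mean(vprobs.argmax(axis=1) == y_val))
            if row["val_top1"] > best_val:
                best_val = row["val_top1"]
                best_weights = model.get_weights()
        history.append(row)
        if verbose:
            print(f"epoch {epoch:3d} lr {optimizer.lr:.5f} "
                  f"loss {row['train_loss']:.4f} top1 {top1:.3f}"
                  + (f" val_top1 {row.get('val_top1', float('nan')):.3f}"
                     if 'val_top1' in row else ""))
    if restore_best and best_weights is not None:
        model.set_weights(best_weights)
    return history
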