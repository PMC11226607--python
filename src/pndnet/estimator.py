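"""Scikit-learn style estimator for the region-pyramid graph classifier.

``PNDNetClassifier`` takes raw RGB image batches (N, H, W, 3) with values
in [0, 255] and integer/array-like labels, handles preprocessing
internally, and follows the sklearn estimator contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``clone``
compatibility), so it composes with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_random_state

from .data import IMAGENET_BGR_MEANS, preprocess
from .network import ModelConfig, PNDNetModel, TrainConfig, train
from .regions import RegionConfig

__all__ = ["PNDNetClassifier"]


class PNDNetClassifier(ClassifierMixin, BaseEstimator):
    """CNN-feature graph-convolution image classifier.

    Parameters
    ----------
    backbone : str, default "tiny"
        Feature extractor name. Only ``"tiny"`` is runnable in this
        installation; the ImageNet architectures are geometry/counting
        adapters (see :mod:`pndnet.backbones`).
    image_size : int, default 64
        Side length expected of the input images.
    upsample_size, region_grid, pyramid_levels, pool_mode
        Geometry of the region/pyramid stage; node count
        P = i^2 + j^2 (13 by default). ``use_spp=False`` bypasses the
        pyramid (nodes are the g*g region descriptors).
    gcn_layers, gcn_features, use_gcn
        Depth and width of the graph module; ``gcn_features=None`` keeps
        the backbone channel width. ``use_gcn=False`` is the no-graph
        ablation.
    dropout_rate, head_norm
        Head regularization: dropout rate in [0, 1) and "layer" / "batch" /
        "none" normalization of the pooled feature vector.
    preprocessing : {"caffe", "caffe_scaled", "none"}
        "caffe" is the BGR zero-centering convention of the reference
        pipeline; "caffe_scaled" (default) additionally divides by 255,
        which keeps activations O(1) for the from-scratch tiny backbone.
    learning_rate, momentum, lr_drop_factor, lr_drop_epoch, epochs,
    batch_size, validation_fraction
        SGD protocol; the rate is divided by ``lr_drop_factor`` after
        ``lr_drop_epoch`` epochs, with no early stopping. When
        ``validation_fraction`` > 0, a stratified validation split is
        carved from the training data and the best-validation weights are
        restored after training.
    random_state : int or None
        Seeds weight initialization, batch shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of unique labels.
    model_ : the assembled numpy model.
    history_ : list of per-epoch dicts (loss, top-1, learning rate).
    n_features_in_ : flattened input dimensionality (sklearn convention).
    """

    def __init__(self, backbone: str = "tiny", image_size: int = 64,
                 upsample_size: int = 16, region_grid: int = 4,
                 pyramid_levels: tuple[int, int] = (2, 3),
                 pool_mode: str = "average", use_spp: bool = True,
                 gcn_layers: int = 2, gcn_features: int | None = None,
                 use_gcn: bool = True, dropout_rate: float = 0.3,
                 head_norm: str = "layer", preprocessing: str = "caffe_scaled",
                 learning_rate: float = 0.005, momentum: float = 0.9,
                 lr_drop_factor: float = 5.0, lr_drop_epoch: int = 100,
                 epochs: int = 50, batch_size: int = 12,
                 validation_fraction: float = 0.0,
                 random_state: int | None = None, verbose: int = 0):
        self.backbone = backbone
        self.image_size = image_size
        self.upsample_size = upsample_size
        self.region_grid = region_grid
        self.pyramid_levels = pyramid_levels
        self.pool_mode = pool_mode
        self.use_spp = use_spp
        self.gcn_layers = gcn_layers
        self.gcn_features = gcn_features
        self.use_gcn = use_gcn
        self.dropout_rate = dropout_rate
        self.head_norm = head_norm
        self.preprocessing = preprocessing
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lr_drop_factor = lr_drop_factor
        self.lr_drop_epoch = lr_drop_epoch
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be an (N, H, W, 3) RGB batch, got shape {X.shape}")
        if X.shape[1] != self.image_size or X.shape[2] != self.image_size:
            raise ValueError(f"images must be {self.image_size}x{self.image_size}, "
                             f"got {X.shape[1]}x{X.shape[2]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X.astype(float)

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        if self.preprocessing == "none":
            return X
        Xp = preprocess(X, IMAGENET_BGR_MEANS)
        if self.preprocessing == "caffe_scaled":
            Xp = Xp / 255.0
        elif self.preprocessing != "caffe":
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        return Xp

    def _model_config(self, n_classes: int, seed: int) -> ModelConfig:
        region = RegionConfig(upsample_size=self.upsample_size,
                              grid=self.region_grid,
                              pyramid_levels=tuple(self.pyramid_levels),
                              pool_mode=self.pool_mode,
                              use_spp=self.use_spp)
        return ModelConfig(backbone=self.backbone, image_size=self.image_size,
                           region=region, gcn_layers=self.gcn_layers,
                           gcn_features=self.gcn_features, use_gcn=self.use_gcn,
                           num_classes=n_classes, dropout_rate=self.dropout_rate,
                           head_norm=self.head_norm, seed=seed)

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = self._validate_images(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError(f"X and y disagree on sample count: {len(X)} vs {len(y)}")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        rs = check_random_state(self.random_state)
        seed = int(rs.randint(0, 2**31 - 1))
        self.n_features_in_ = int(np.prod(X.shape[1:]))

        Xp = self._preprocess(X)
        X_val = y_val = None
        if self.validation_fraction > 0:
            from .data import make_split
            plan = make_split(y_enc, test_fraction=self.validation_fraction, seed=seed)
            X_val, y_val = Xp[plan.test_ids], y_enc[plan.test_ids]
            Xp, y_enc = Xp[plan.train_ids], y_enc[plan.train_ids]

        self.model_ = PNDNetModel(self._model_config(len(self.classes_), seed))
        tc = TrainConfig(learning_rate=self.learning_rate, momentum=self.momentum,
                         lr_drop_factor=self.lr_drop_factor,
                         lr_drop_epoch=self.lr_drop_epoch, epochs=self.epochs,
                         batch_size=self.batch_size, seed=seed)
        self.history_ = train(self.model_, Xp, y_enc, tc, X_val=X_val, y_val=y_val,
                              verbose=bool(self.verbose))
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this PNDNetClassifier instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_images(X)
        return self.model_.predict_proba(self._preprocess(X))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Penultimate (post-normalization) feature vectors, one per image."""
        self._check_fitted()
        X = self._validate_images(X)
        feats = []
        Xp = self._preprocess(X)
        for i in range(0, len(Xp), 64):
            self.model_.forward(Xp[i:i + 64], train=False)
            feats.append(self.model_.penultimate_.copy())
        return np.vstack(feats)

    def n_parameters(self) -> int:
        self._check_fitted()
        return self.model_.n_parameters()
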