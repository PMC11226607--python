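"""Dataset indexing, splitting, preprocessing and augmentation.

Datasets are plain class-per-folder image trees (one subdirectory per
class, PNG/JPEG inside). Splitting follows the evaluation protocol used
throughout: a stratified 70:30 train/test division, and a stratified
five-fold partition of the training pool (4:1 train/validation per fold)
with the test set held fixed across folds.

Preprocessing follows the Keras-applications "caffe" convention: channels
reordered RGB->BGR, then zero-centered with the ImageNet channel means
(103.939, 116.779, 123.68 in BGR order), with no scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "IMAGENET_BGR_MEANS",
    "DatasetIndex",
    "SplitPlan",
    "AugmentConfig",
    "index_dataset",
    "load_images",
    "make_split",
    "make_folds",
    "preprocess",
    "augment",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}
IMAGENET_BGR_MEANS = np.array([103.939, 116.779, 123.68])


@dataclass
class DatasetIndex:
    """Enumeration of a class-per-folder tree; class ids are dense and
    follow lexicographic folder order."""

    records: list[tuple[Path, int]]
    class_names: list[str]
    skipped: list[Path] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([label for _, label in self.records], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SplitPlan:
    """Disjoint train/test index sets, optionally with K stratified
    (train, validation) folds partitioning the training pool."""

    train_ids: list[int]
    test_ids: list[int]
    seed: int
    val_ids: list[int] = field(default_factory=list)
    folds: list[tuple[list[int], list[int]]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_ids": list(map(int, self.train_ids)),
            "val_ids": list(map(int, self.val_ids)),
            "test_ids": list(map(int, self.test_ids)),
            "seed": int(self.seed),
            "folds": [[list(map(int, tr)), list(map(int, va))] for tr, va in self.folds],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_ids=payload["train_ids"],
            test_ids=payload["test_ids"],
            seed=payload["seed"],
            val_ids=payload.get("val_ids", []),
            folds=[(tr, va) for tr, va in payload.get("folds", [])],
        )


@dataclass(frozen=True)
class AugmentConfig:
    """On-the-fly augmentation magnitudes.

    Defaults follow the training hyper-parameter table (rotation 20 deg,
    scale 0.20, translation 0.20, random flip, Gaussian noise); Gaussian
    blur is available as an alternative smoothing augmentation
    (``blur_sigma`` > 0). The final step is a random crop to ``crop_size``.
    """

    rotation_deg: float = 20.0
    scale_frac: float = 0.20
    translation_frac: float = 0.20
    flip: bool = True
    gaussian_noise_sd: float = 8.0
    blur_sigma: float = 0.0
    crop_size: int = 224

    def __post_init__(self):
        for name in ("rotation_deg", "scale_frac", "translation_frac",
                     "gaussian_noise_sd", "blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.crop_size < 1:
            raise ValueError("crop_size must be positive")


def index_dataset(root: str | Path) -> DatasetIndex:
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class subdirectories")
    records: list[tuple[Path, int]] = []
    skipped: list[Path] = []
    class_names = [d.name for d in class_dirs]
    for cid, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
        kept = 0
        for p in files:
            try:
                with Image.open(p) as im:
                    im.verify()
            except Exception:
                skipped.append(p)
                continue
            records.append((p, cid))
            kept += 1
        if kept == 0:
            raise ValueError(f"class folder {d} contains no readable images")
    return DatasetIndex(records=records, class_names=class_names, skipped=skipped)


def load_images(index: DatasetIndex, ids=None, size: int | None = None) -> np.ndarray:
    """Decode images as (N, H, W, 3) uint8, bilinearly resized to
    ``size`` x ``size`` when given."""
    ids = range(len(index)) if ids is None else ids
    out = []
    for i in ids:
        path, _ = index.records[i]
        with Image.open(path) as im:
            im = im.convert("RGB")
            if size is not None:
                im = im.resize((size, size), Image.BILINEAR)
            out.append(np.asarray(im, dtype=np.uint8))
    return np.stack(out)


def _per_class_ids(labels: np.ndarray) -> dict[int, np.ndarray]:
    return {int(c): np.flatnonzero(labels == c) for c in np.unique(labels)}


def make_split(index: DatasetIndex | np.ndarray, test_fraction: float = 0.30,
               seed: int = 0) -> SplitPlan:
    """Stratified train/test split: per class, round(test_fraction * n)
    images go to the test set; deterministic under ``seed``."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = index.labels if isinstance(index, DatasetIndex) else np.asarray(index)
    rng = np.random.default_rng(seed)
    train_ids: list[int] = []
    test_ids: list[int] = []
    for c, ids in sorted(_per_class_ids(labels).items()):
        if len(ids) < 2:
            raise ValueError(f"class {c} has fewer than 2 images; cannot split")
        ids = rng.permutation(ids)
        n_test = int(np.floor(test_fraction * len(ids) + 0.5))
        n_test = min(max(n_test, 1), len(ids) - 1)   # keep both sides nonempty
        test_ids.extend(int(i) for i in ids[:n_test])
        train_ids.extend(int(i) for i in ids[n_test:])
    return SplitPlan(train_ids=sorted(train_ids), test_ids=sorted(test_ids), seed=seed)


def make_folds(plan: SplitPlan, labels: np.ndarray, k: int = 5) -> SplitPlan:
    """Attach k stratified cross-validation folds over the training pool.

    Per class, images are dealt into k nearly equal validation chunks;
    per-class remainders are assigned to the currently smallest folds so
    that fold TOTALS are as equal as possible (a pool of 2010 yields
    exactly 402 validation / 1608 training images per fold). The test set
    is untouched. The fold validation sets partition the training pool.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    rng = np.random.default_rng(plan.seed)
    pool = np.asarray(plan.train_ids)
    fold_members: list[list[int]] = [[] for _ in range(k)]
    fold_sizes = np.zeros(k, dtype=int)
    for c, ids in sorted(_per_class_ids(labels[pool]).items()):
        ids = rng.permutation(pool[ids])
        if len(ids) < k:
            raise ValueError(f"class {c} has {len(ids)} training images, fewer than k={k}")
        base, rem = divmod(len(ids), k)
        # folds currently smallest take one extra sample each
        order = np.lexsort((np.arange(k), fold_sizes))
        take = np.full(k, base)
        take[order[:rem]] += 1
        start = 0
        for f in range(k):
            fold_members[f].extend(int(i) for i in ids[start:start + take[f]])
            start += take[f]
            fold_sizes[f] += take[f]
    folds = []
    for f in range(k):
        val = sorted(fold_members[f])
        train = sorted(set(map(int, pool)) - set(val))
        folds.append((train, val))
    return SplitPlan(train_ids=list(plan.train_ids), test_ids=list(plan.test_ids),
                     seed=plan.seed, folds=folds)


def preprocess(image: np.ndarray, means: np.ndarray = IMAGENET_BGR_MEANS) -> np.ndarray:
    """RGB->BGR channel reorder then per-channel zero-centering (no scaling).

    Accepts a single HxWx3 image or an NHWC batch, values in [0, 255].
    """
    image = np.asarray(image, dtype=float)
    if image.shape[-1] != 3:
        raise ValueError(f"expected 3 channels last, got shape {image.shape}")
    return image[..., ::-1] - means


def augment(image: np.ndarray, cfg: AugmentConfig, seed: int) -> np.ndarray:
    """Random rotation/scale/translation/flip/noise then a random crop.

    Deterministic under the per-call ``seed``. With all magnitudes zero and
    ``crop_size`` equal to the source size this is the identity.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected a single HxWx3 image, got shape {image.shape}")
    h, w = image.shape[:2]
    if cfg.crop_size > min(h, w):
        raise ValueError(f"crop_size {cfg.crop_size} exceeds image size {(h, w)}")
    rng = np.random.default_rng(seed)

    angle = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)) \
        if cfg.rotation_deg else 0.0
    scale = 1.0 + (rng.uniform(-cfg.scale_frac, cfg.scale_frac) if cfg.scale_frac else 0.0)
    tx = rng.uniform(-cfg.translation_frac, cfg.translation_frac) * w \
        if cfg.translation_frac else 0.0
    ty = rng.uniform(-cfg.translation_frac, cfg.translation_frac) * h \
        if cfg.translation_frac else 0.0

    if angle or scale != 1.0 or tx or ty:
        # output->input coordinate map about the image center, linear interpolation
        cos, sin = np.cos(angle), np.sin(angle)
        M = np.array([[cos, -sin], [sin, cos]]) / scale
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - M @ (center + np.array([ty, tx]))
        out = np.empty_like(image)
        for ch in range(3):
            out[..., ch] = ndimage.affine_transform(
                image[..., ch], M, offset=offset, order=1, mode="reflect")
        image = out

    if cfg.flip and rng.random() < 0.5:
        image = image[:, ::-1, :]
    if cfg.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    if cfg.gaussian_noise_sd > 0:
        image = image + rng.normal(0.0, cfg.gaussian_noise_sd, image.shape)

    cs = cfg.crop_size
    top = int(rng.integers(0, h - cs + 1))
    left = int(rng.integers(0, w - cs + 1))
    return np.clip(image[top:top + cs, left:left + cs, :], 0, 255)
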