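"""Dataset indexing, stratified splitting, fold partitions, preprocessing
and augmentation."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from pndnet import (AugmentConfig, SplitPlan, augment, index_dataset,
                    load_images, make_folds, make_split, preprocess)
from pndnet.data import IMAGENET_BGR_MEANS


# -- indexing ---------------------------------------------------------------

def test_index_counts_and_order(leaf8_tree):
    idx = index_dataset(leaf8_tree)
    assert len(idx) == 32
    assert len(idx.class_names) == 8
    assert idx.class_names == sorted(idx.class_names)
    idx2 = index_dataset(leaf8_tree)
    assert [r for r in idx.records] == [r for r in idx2.records]


def test_index_rejects_empty_class(tmp_path):
    (tmp_path / "class_a").mkdir()
    (tmp_path / "class_b").mkdir()
    from PIL import Image
    Image.new("RGB", (8, 8)).save(tmp_path / "class_a" / "x.png")
    with pytest.raises(ValueError, match="no readable images"):
        index_dataset(tmp_path)


def test_index_reports_unreadable_images(tmp_path):
    from PIL import Image
    d = tmp_path / "c0"
    d.mkdir()
    Image.new("RGB", (8, 8)).save(d / "good.png")
    (d / "broken.png").write_bytes(b"not a png")
    idx = index_dataset(tmp_path)
    assert len(idx) == 1
    assert [p.name for p in idx.skipped] == ["broken.png"]


def test_load_images_resizes(leaf8_tree):
    idx = index_dataset(leaf8_tree)
    X = load_images(idx, ids=[0, 1], size=32)
    assert X.shape == (2, 32, 32, 3) and X.dtype == np.uint8


# -- splitting --------------------------------------------------------------

def test_split_stratified_arithmetic():
    labels = np.repeat([0, 1], 50)
    plan = make_split(labels, test_fraction=0.30, seed=0)
    assert len(plan.train_ids) == 70 and len(plan.test_ids) == 30
    test_labels = labels[plan.test_ids]
    assert np.bincount(test_labels).tolist() == [15, 15]
    assert set(plan.train_ids).isdisjoint(plan.test_ids)


def test_split_deterministic_and_eight_class():
    labels = np.repeat(np.arange(8), 50)
    p1 = make_split(labels, 0.30, seed=9)
    p2 = make_split(labels, 0.30, seed=9)
    assert p1.train_ids == p2.train_ids and p1.test_ids == p2.test_ids
    assert len(p1.train_ids) == 280 and len(p1.test_ids) == 120


def test_split_rejects_tiny_class():
    with pytest.raises(ValueError, match="fewer than 2"):
        make_split(np.array([0, 0, 1]), 0.3, seed=0)


def test_folds_partition_training_pool():
    labels = np.repeat(np.arange(4), 25)
    plan = make_folds(make_split(labels, 0.2, seed=1), labels, k=5)
    pool = set(plan.train_ids)
    union = set()
    for tr, va in plan.folds:
        assert set(tr).isdisjoint(va)
        assert set(tr) | set(va) == pool
        union |= set(va)
        assert set(va).isdisjoint(plan.test_ids)
    assert union == pool


def test_fivefold_sizes_match_reference_protocol():
    """A 2010-image training pool yields exactly 1608/402 per fold."""
    counts = [402, 350, 300, 290, 280, 208, 180]   # 7 classes, sum 2010
    labels = np.repeat(np.arange(7), counts)
    plan = SplitPlan(train_ids=list(range(2010)), test_ids=[], seed=0)
    plan = make_folds(plan, labels, k=5)
    for tr, va in plan.folds:
        assert len(tr) == 1608 and len(va) == 402


def test_folds_agree_with_sklearn_on_balanced_pool():
    """On a balanced pool both allocators produce the same fold sizes and
    per-class stratification."""
    labels = np.repeat(np.arange(5), 20)
    plan = make_folds(make_split(labels, 0.2, seed=3), labels, k=4)
    pool = np.asarray(plan.train_ids)
    skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=3)
    sk_sizes = sorted(len(va) for _, va in skf.split(pool, labels[pool]))
    my_sizes = sorted(len(va) for _, va in plan.folds)
    assert my_sizes == sk_sizes
    for _, va in plan.folds:
        assert np.bincount(labels[va], minlength=5).tolist() == [4] * 5


def test_folds_reject_small_class():
    labels = np.repeat([0, 1], [3, 50])
    plan = make_split(labels, 0.3, seed=0)
    with pytest.raises(ValueError, match="fewer than k"):
        make_folds(plan, labels, k=5)


def test_split_plan_json_roundtrip(tmp_path):
    labels = np.repeat([0, 1], 10)
    plan = make_folds(make_split(labels, 0.3, seed=2), labels, k=2)
    plan.to_json(tmp_path / "plan.json")
    back = SplitPlan.from_json(tmp_path / "plan.json")
    assert back.train_ids == plan.train_ids
    assert back.folds == [(list(tr), list(va)) for tr, va in plan.folds]


# -- preprocessing ----------------------------------------------------------

def test_preprocess_zero_centering_identity():
    img = np.empty((4, 4, 3))
    img[..., 0], img[..., 1], img[..., 2] = 123.68, 116.779, 103.939  # RGB means
    np.testing.assert_allclose(preprocess(img), 0.0, atol=1e-12)


def test_preprocess_channel_swap():
    img = np.zeros((1, 1, 3))
    img[0, 0, 0] = 200.0  # pure red
    out = preprocess(img) + IMAGENET_BGR_MEANS
    assert out[0, 0, 2] == 200.0 and out[0, 0, 0] == 0.0


def test_preprocess_centers_imagenet_like_sample(rng):
    """Per-channel output means vanish for inputs distributed around the
    ImageNet channel means."""
    rgb_means = IMAGENET_BGR_MEANS[::-1]
    X = rng.normal(loc=rgb_means, scale=20.0, size=(200, 8, 8, 3))
    out = preprocess(X)
    assert np.all(np.abs(out.mean(axis=(0, 1, 2))) < 1.0)


def test_preprocess_rejects_bad_channels():
    with pytest.raises(ValueError):
        preprocess(np.zeros((4, 4, 4)))


# -- augmentation -----------------------------------------------------------

def _identity_cfg(size):
    return AugmentConfig(rotation_deg=0, scale_frac=0, translation_frac=0,
                         flip=False, gaussian_noise_sd=0, blur_sigma=0,
                         crop_size=size)


def test_augment_zero_magnitudes_is_identity(rng):
    img = rng.uniform(0, 255, size=(32, 32, 3))
    np.testing.assert_allclose(augment(img, _identity_cfg(32), seed=0), img)


def test_augment_crop_shape_and_determinism(rng):
    img = rng.uniform(0, 255, size=(64, 64, 3))
    cfg = AugmentConfig(crop_size=48)
    out1 = augment(img, cfg, seed=5)
    out2 = augment(img, cfg, seed=5)
    assert out1.shape == (48, 48, 3)
    np.testing.assert_array_equal(out1, out2)
    assert not np.array_equal(out1, augment(img, cfg, seed=6))


def test_augment_rejects_oversized_crop(rng):
    img = rng.uniform(0, 255, size=(32, 32, 3))
    with pytest.raises(ValueError, match="crop_size"):
        augment(img, AugmentConfig(crop_size=64), seed=0)


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(rotation_deg=-1)
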