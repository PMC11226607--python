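"""Metrics, top-k, protocols, Grad-CAM and t-SNE export."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from pndnet import (ConfusionMatrix, PNDNetClassifier, confusion,
                    evaluate_predictions, gradcam, make_folds, make_split,
                    metrics_from_confusion, run_protocol, topk_accuracy,
                    tsne_export)


# -- confusion matrix -------------------------------------------------------

def test_confusion_examples():
    cm = confusion([0, 1, 1], [0, 1, 0], 2)
    assert cm.counts[0, 0] == 1 and cm.counts[1, 1] == 1 and cm.counts[1, 0] == 1
    assert cm.total == 3
    perfect = confusion([0, 1, 2], [0, 1, 2], 3)
    assert np.all(perfect.counts == np.eye(3))


def test_confusion_row_sums_are_class_counts(rng):
    y = rng.integers(0, 4, size=100)
    p = rng.integers(0, 4, size=100)
    cm = confusion(y, p, 4)
    np.testing.assert_array_equal(cm.counts.sum(axis=1), np.bincount(y, minlength=4))


def test_confusion_rejects_out_of_range():
    with pytest.raises(ValueError):
        confusion([0, 3], [0, 1], 3)


# -- metrics ----------------------------------------------------------------

def test_metrics_hand_arithmetic():
    # binary: class 0 has TP=5, FP=5, FN=0
    cm = ConfusionMatrix(np.array([[5, 0], [5, 0]]))
    rep = metrics_from_confusion(cm)
    assert rep.precision[0] == pytest.approx(0.5)
    assert rep.recall[0] == pytest.approx(1.0)
    assert rep.f1[0] == pytest.approx(2 * 0.5 * 1.0 / 1.5)


def test_metrics_accuracy_from_counts():
    # one-vs-rest counts TP=90, TN=5, FP=3, FN=2 -> accuracy 0.95
    cm = ConfusionMatrix(np.array([[90, 2], [3, 5]]))
    rep = metrics_from_confusion(cm)
    assert rep.top1 == pytest.approx(0.95)


def test_metrics_perfect_classifier():
    rep = metrics_from_confusion(confusion([0, 1, 2], [0, 1, 2], 3))
    assert rep.top1 == 1.0
    assert np.all(rep.precision == 1.0) and np.all(rep.recall == 1.0)
    assert rep.macro_f1 == 1.0


def test_metrics_zero_division_convention():
    # class 2 never predicted nor present
    rep = metrics_from_confusion(confusion([0, 1], [0, 1], 3))
    assert rep.precision[2] == 0.0 and rep.recall[2] == 0.0 and rep.f1[2] == 0.0


def test_metrics_match_per_sample_tally(rng):
    """Confusion-derived metrics equal an independent per-sample TP/FP/FN
    tally (via sklearn) on 1000 random label sets."""
    for _ in range(1000):
        Y = int(rng.integers(2, 6))
        n = int(rng.integers(5, 30))
        y = rng.integers(0, Y, size=n)
        p = rng.integers(0, Y, size=n)
        rep = metrics_from_confusion(confusion(y, p, Y))
        prec, rec, f1, _ = precision_recall_fscore_support(
            y, p, labels=range(Y), zero_division=0)
        np.testing.assert_allclose(rep.precision, prec, atol=1e-12)
        np.testing.assert_allclose(rep.recall, rec, atol=1e-12)
        np.testing.assert_allclose(rep.f1, f1, atol=1e-12)
        assert rep.top1 == pytest.approx(np.mean(y == p))


def test_metrics_macro_f1_within_per_class_range(rng):
    y = rng.integers(0, 5, size=200)
    p = rng.integers(0, 5, size=200)
    rep = metrics_from_confusion(confusion(y, p, 5))
    assert rep.f1.min() - 1e-12 <= rep.macro_f1 <= rep.f1.max() + 1e-12


def test_empty_confusion_rejected():
    with pytest.raises(ValueError):
        metrics_from_confusion(ConfusionMatrix(np.zeros((2, 2), dtype=int)))


# -- top-k ------------------------------------------------------------------

def test_topk_equals_one_at_k_equals_y(rng):
    probs = rng.dirichlet(np.ones(5), size=40)
    y = rng.integers(0, 5, size=40)
    assert topk_accuracy(probs, y, 5) == 1.0


def test_top1_equals_argmax_accuracy(rng):
    probs = rng.dirichlet(np.ones(4), size=60)
    y = rng.integers(0, 4, size=60)
    assert topk_accuracy(probs, y, 1) == pytest.approx(
        np.mean(probs.argmax(axis=1) == y))


def test_topk_ties_break_toward_lower_class_index():
    probs = np.array([[0.25, 0.25, 0.25, 0.25]])
    assert topk_accuracy(probs, [1], 2) == 1.0   # ties -> classes 0, 1
    assert topk_accuracy(probs, [3], 2) == 0.0


def test_topk_random_uniform_approaches_k_over_y(rng):
    n = 20000
    probs = rng.dirichlet(np.ones(10), size=n)
    y = rng.integers(0, 10, size=n)
    acc = topk_accuracy(probs, y, 3)
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(acc - 0.3) < 3 * se + 1e-9


def test_topk_validation(rng):
    probs = rng.dirichlet(np.ones(3), size=5)
    with pytest.raises(ValueError):
        topk_accuracy(probs, [0] * 5, 0)
    with pytest.raises(ValueError):
        topk_accuracy(probs, [0] * 5, 4)


def test_top3_at_least_top1(rng):
    probs = rng.dirichlet(np.ones(6), size=100)
    y = rng.integers(0, 6, size=100)
    rep = evaluate_predictions(probs, y, 6)
    assert rep.top3 >= rep.top1


# -- protocols --------------------------------------------------------------

def _fast_estimator(**kw):
    base = dict(epochs=10, random_state=0)
    base.update(kw)
    return PNDNetClassifier(**base)


def test_holdout_protocol_beats_chance(leaf3, tmp_path):
    X, y = leaf3
    plan = make_split(y, test_fraction=0.3, seed=0)
    report = run_protocol(_fast_estimator(epochs=50), X, y, plan,
                          mode="holdout", out_dir=tmp_path)
    assert report["test"]["top1"] > 1.0 / 3
    assert report["test"]["top3"] >= report["test"]["top1"]
    assert (tmp_path / "report_holdout.json").exists()


def test_kfold_protocol_rows_and_average(leaf3, tmp_path):
    X, y = leaf3
    plan = make_folds(make_split(y, 0.3, seed=1), y, k=3)
    report = run_protocol(_fast_estimator(epochs=3), X, y, plan,
                          mode="kfold", out_dir=tmp_path)
    assert len(report["folds"]) == 3
    for key in ("val_top1", "test_top1", "f1"):
        vals = [r[key] for r in report["folds"]]
        assert report["average"][key] == pytest.approx(np.mean(vals))
    assert (tmp_path / "report_kfold.csv").exists()


def test_kfold_requires_folds(leaf3):
    X, y = leaf3
    plan = make_split(y, 0.3, seed=1)
    with pytest.raises(ValueError, match="no folds"):
        run_protocol(_fast_estimator(), X, y, plan, mode="kfold")


# -- explanation ------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted(leaf3):
    X, y = leaf3
    clf = PNDNetClassifier(epochs=10, random_state=0)
    clf.fit(X, y)
    return clf


def test_gradcam_shape_and_range(fitted, leaf3):
    X, _ = leaf3
    heat = gradcam(fitted, X[0], 0)
    assert heat.shape == (64, 64)
    assert heat.min() >= 0.0 and heat.max() <= 1.0
    assert heat.max() == pytest.approx(1.0, abs=1e-9) or heat.max() == 0.0


def test_gradcam_constant_map_collapses_to_zero():
    """Uniform activations with uniform positive gradients produce a
    constant weighted map, which the normalization guard sends to zero."""
    class _Const:
        feature_map_ = None
        feature_map_grad_ = None

        def forward(self, x, train=False):
            self.feature_map_ = np.ones((1, 4, 4, 8))
            return np.zeros((1, 3))

        def backward(self, seed, into_backbone=True):
            self.feature_map_grad_ = np.ones((1, 4, 4, 8))

    heat = gradcam(_Const(), np.zeros((16, 16, 3)), 0)
    np.testing.assert_array_equal(heat, np.zeros((16, 16)))


def test_gradcam_validates_target(fitted, leaf3):
    X, _ = leaf3
    with pytest.raises(ValueError, match="target class"):
        gradcam(fitted, X[0], 7)


def test_tsne_rows_determinism_and_duplicates(fitted, leaf3, tmp_path):
    X, y = leaf3
    Xd = np.concatenate([X[:12], X[:1]])       # duplicate of sample 0
    yd = np.concatenate([y[:12], y[:1]])
    df1 = tsne_export(fitted, Xd, yd, seed=3, out_path=tmp_path / "t.csv")
    df2 = tsne_export(fitted, Xd, yd, seed=3)
    assert len(df1) == 13
    np.testing.assert_allclose(df1[["x", "y"]].values, df2[["x", "y"]].values)
    assert (tmp_path / "t.csv").exists()
    # duplicated points embed closer than the typical pair
    emb = df1[["x", "y"]].values
    dup = np.linalg.norm(emb[0] - emb[12])
    from scipy.spatial.distance import pdist
    assert dup < np.median(pdist(emb))


def test_tsne_rejects_tiny_sample(fitted, leaf3):
    X, y = leaf3
    with pytest.raises(ValueError, match="at least 10"):
        tsne_export(fitted, X[:5], y[:5])
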