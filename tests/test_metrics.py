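"""Evaluation metrics: AUC, confusion-table metrics, Dice, HD95."""

import numpy as np
import pytest

from omtapc.metrics import auc, auc_ci, confusion_metrics, dice, hd95


def _brute_force_auc(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_and_inverted():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == 0.0


def test_auc_matches_pairwise_oracle(rng):
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    s = np.round(rng.uniform(size=50), 2)  # rounding forces ties
    assert auc(y, s) == pytest.approx(_brute_force_auc(y, s), abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    y = rng.integers(0, 2, 80)
    y[:2] = [0, 1]
    s = rng.normal(size=80)
    assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    s = rng.normal(size=40)
    assert auc(y, s) == pytest.approx(auc(y, np.exp(2.0 * s)), abs=1e-12)


def test_auc_single_class_undefined():
    assert auc([1, 1, 1], [0.1, 0.2, 0.3]) is None


def test_auc_ci_brackets_point_estimate(rng):
    y = np.array([0] * 20 + [1] * 20)
    s = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)])
    point = auc(y, s)
    lo, hi = auc_ci(y, s, n_boot=300, seed=1)
    assert lo <= point <= hi


def test_confusion_perfect_classifier():
    r = confusion_metrics([0, 1, 1, 0], [0.1, 0.9, 0.8, 0.2])
    assert (r.acc, r.sens, r.spec, r.ppv, r.npv, r.f1) == (1.0,) * 6
    assert (r.tp, r.fp, r.tn, r.fn) == (2, 0, 2, 0)


def test_confusion_undefined_cells_flagged():
    # no positive predictions: PPV undefined, specificity computable
    r = confusion_metrics([0, 1, 0], [0.1, 0.2, 0.3], threshold=0.9)
    assert r.ppv is None
    assert r.spec == 1.0
    assert r.sens == 0.0


def test_confusion_matches_hand_formulas(rng):
    y = rng.integers(0, 2, 60)
    s = rng.uniform(size=60)
    r = confusion_metrics(y, s, threshold=0.4)
    tp, fp, tn, fn = r.tp, r.fp, r.tn, r.fn
    assert tp + fp + tn + fn == 60
    assert r.acc == pytest.approx((tp + tn) / 60)
    if tp + fn:
        assert r.sens == pytest.approx(tp / (tp + fn))
    if tn + fp:
        assert r.spec == pytest.approx(tn / (tn + fp))
    if r.ppv is not None and r.sens and (r.ppv + r.sens):
        assert r.f1 == pytest.approx(2 * r.ppv * r.sens / (r.ppv + r.sens))


def test_confusion_empty_input_rejected():
    with pytest.raises(ValueError):
        confusion_metrics([], [])


def test_dice_identity_disjoint_and_counting():
    a = np.zeros((4, 4, 4), bool)
    a[1:3, 1:3, 1:3] = True
    assert dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = True
    assert dice(a, b) == 0.0
    # 2x1x1 vs 1x1x1 overlapping boxes -> 2*1/(2+1)
    c = np.zeros((4, 1, 1), bool)
    c[0:2] = True
    d = np.zeros_like(c)
    d[0] = True
    assert dice(c, d) == pytest.approx(2.0 / 3.0)
    assert dice(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool)) == 1.0


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        dice(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))


def _brute_force_hd95(a, b, spacing):
    from scipy.ndimage import binary_erosion, generate_binary_structure

    conn = generate_binary_structure(3, 1)
    surf = lambda m: m & ~binary_erosion(m, conn)
    sa = np.argwhere(surf(a)) * spacing
    sb = np.argwhere(surf(b)) * spacing
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
    return np.percentile(d_ab + d_ba, 95)


def test_hd95_identity_and_shifted_cube():
    a = np.zeros((12, 12, 12), bool)
    a[2:5, 2:5, 2:5] = True
    assert hd95(a, a) == 0.0
    b = np.roll(a, 2, axis=0)
    expected = _brute_force_hd95(a, b, np.array([1.0, 1.0, 1.0]))
    assert hd95(a, b) == pytest.approx(expected)


def test_hd95_symmetric_and_spacing_aware():
    a = np.zeros((10, 10, 10), bool)
    a[2:4, 2:4, 2:4] = True
    b = np.roll(a, 3, axis=2)
    assert hd95(a, b) == pytest.approx(hd95(b, a))
    assert hd95(a, b, spacing=(1, 1, 2)) == pytest.approx(2.0 * hd95(a, b), rel=0.2)


def test_hd95_empty_mask_undefined():
    a = np.zeros((5, 5, 5), bool)
    b = np.zeros_like(a)
    b[2, 2, 2] = True
    assert hd95(a, b) is None
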