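"""Algebraic preclassification: unfoldings, SVD features, MvOPLS, scoring."""

import numpy as np
import pytest
from scipy import linalg

from omtapc.apc import (
    APCClassifier,
    ModeFeatures,
    TumorTensor,
    build_weighted_matrices,
    crop_wt_tensor,
    extract_mode_features,
    fit_mvopls,
    label_smooth,
    mode_fold,
    mode_unfold,
    one_hot,
    preclassify,
    svd_feature,
)
from omtapc.transport import OMTTensor


def _random_tensor(rng, m=6):
    return TumorTensor(rng.normal(size=(m, m, m)))


# ---------------------------------------------------------------------------
# unfolding


@pytest.mark.parametrize("s", [1, 2, 3])
def test_unfold_contains_all_entries_once(rng, s):
    T = TumorTensor(np.arange(1.0, 217.0).reshape(6, 6, 6))
    U = mode_unfold(T, s)
    assert U.shape == (6, 36)
    assert sorted(U.ravel()) == sorted(T.values.ravel())
    assert np.linalg.norm(U) == pytest.approx(np.linalg.norm(T.values))


def test_unfold_rank1_structure(rng):
    a, b, c = rng.normal(size=6), rng.normal(size=6), rng.normal(size=6)
    T = TumorTensor(np.einsum("i,j,k->ijk", a, b, c))
    for s in (1, 2, 3):
        assert np.linalg.matrix_rank(mode_unfold(T, s)) == 1


@pytest.mark.parametrize("s", [1, 2, 3])
def test_fold_unfold_roundtrip(rng, s):
    T = _random_tensor(rng)
    assert np.array_equal(mode_fold(mode_unfold(T, s), s, T.values.shape), T.values)


def test_unfold_invalid_mode(rng):
    with pytest.raises(ValueError):
        mode_unfold(_random_tensor(rng), 4)


# ---------------------------------------------------------------------------
# truncated-SVD features


def test_rank1_feature_norm_is_singular_value(rng):
    u = rng.normal(size=8)
    v = rng.normal(size=64)
    M = 3.7 * np.outer(u / np.linalg.norm(u), v / np.linalg.norm(v))
    x, sv = svd_feature(M, 1)
    assert len(x) == 8
    assert np.linalg.norm(x) == pytest.approx(3.7, abs=1e-10)
    assert sv[0] == pytest.approx(3.7, abs=1e-10)


@pytest.mark.parametrize("j", [1, 3, 7])
def test_eckart_young_residual(rng, j):
    """Truncation residual equals the tail singular energy (full-SVD oracle)."""
    M = rng.normal(size=(8, 64))
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    recon = U[:, :j] @ np.diag(S[:j]) @ Vt[:j]
    residual = np.linalg.norm(M - recon) ** 2
    assert residual == pytest.approx(np.sum(S[j:] ** 2), rel=1e-10)
    x, sv = svd_feature(M, j)
    assert np.allclose(np.abs(sv), S[:j])
    assert len(x) == 8 * j


def test_svd_feature_sign_convention(rng):
    M = rng.normal(size=(8, 64))
    x, sv = svd_feature(M, 3)
    U = x.reshape(8, 3, order="F") / sv
    peaks = U[np.argmax(np.abs(U), axis=0), np.arange(3)]
    assert np.all(peaks > 0)


def test_svd_feature_rank_bounds(rng):
    M = rng.normal(size=(8, 64))
    with pytest.raises(ValueError):
        svd_feature(M, 8)
    with pytest.raises(ValueError):
        svd_feature(M, 0)


# ---------------------------------------------------------------------------
# weighted matrices


def _features(rng, n, d=6):
    return [
        ModeFeatures(
            rng.normal(size=d), rng.normal(size=d), rng.normal(size=d),
            j=2, singular_values=np.zeros((3, 2)),
        )
        for _ in range(n)
    ]


def test_class_weights_sum_to_one_per_class(rng):
    feats = _features(rng, 7)
    labels = [one_hot(l) for l in (0, 0, 0, 1, 1, 1, 1)]
    X, Y, w = build_weighted_matrices(feats, labels)
    assert w[:3].sum() == pytest.approx(1.0)
    assert w[3:].sum() == pytest.approx(1.0)
    # balanced case: weighting reduces to a global scalar
    feats2 = _features(rng, 4)
    _, _, w2 = build_weighted_matrices(feats2, [one_hot(l) for l in (0, 0, 1, 1)])
    assert np.allclose(w2, 0.5)


def test_duplicating_a_class_preserves_its_column_sum(rng):
    feats = _features(rng, 5)
    labels = [one_hot(l) for l in (0, 0, 1, 1, 1)]
    _, Y, _ = build_weighted_matrices(feats, labels)
    sum0 = Y[:, [0, 1]].sum(axis=1)
    feats_dup = feats + [feats[0], feats[1]]
    labels_dup = labels + [one_hot(0), one_hot(0)]
    _, Y2, _ = build_weighted_matrices(feats_dup, labels_dup)
    sum0_dup = Y2[:, [0, 1, 5, 6]].sum(axis=1)
    assert np.allclose(sum0, sum0_dup)


def test_single_class_rejected(rng):
    feats = _features(rng, 3)
    with pytest.raises(ValueError):
        build_weighted_matrices(feats, [one_hot(0)] * 3)


# ---------------------------------------------------------------------------
# MvOPLS / generalized eigenvalue problem


def _toy_problem(rng, d=3, n=8):
    labels = [one_hot(i % 2) for i in range(n)]
    feats = _features(rng, n, d=d)
    X, Y, _ = build_weighted_matrices(feats, labels)
    return X[:d], X[d : 2 * d], X[2 * d :], Y


def test_constraint_satisfaction(rng):
    X1, X2, X3, Y = _toy_problem(rng)
    model = fit_mvopls(X1, X2, X3, Y, k=2)
    d = 3
    B = np.zeros((9, 9))
    for s, Xs in enumerate((X1, X2, X3)):
        B[s * d : (s + 1) * d, s * d : (s + 1) * d] = Xs @ Xs.T + 1e-4 * np.eye(d)
    assert np.allclose(model.P_star.T @ B @ model.P_star, np.eye(2), atol=1e-10)


def test_trace_objective_matches_dense_gep_oracle(rng):
    """tr(P*ᵀAP*) equals the top-k eigenvalue sum of the dense pencil."""
    X1, X2, X3, Y = _toy_problem(rng)
    model = fit_mvopls(X1, X2, X3, Y, k=2)
    d = 3
    X = np.concatenate([X1, X2, X3])
    A = X @ Y.T @ Y @ X.T
    B = np.zeros((9, 9))
    for s, Xs in enumerate((X1, X2, X3)):
        B[s * d : (s + 1) * d, s * d : (s + 1) * d] = Xs @ Xs.T + 1e-4 * np.eye(d)
    evals = linalg.eigh(A, B, eigvals_only=True)
    expected = evals[-2:].sum()
    assert model.objective == pytest.approx(expected, abs=1e-10)


def _eq2_objective(P, W, views, Y, gammas, d):
    total = 0.0
    for s, (Xs, g) in enumerate(zip(views, gammas)):
        Ps = P[s * d : (s + 1) * d]
        total += np.linalg.norm(Y - W.T @ Ps.T @ Xs) ** 2
        total += g * np.linalg.norm(Ps @ W) ** 2
    return total


def test_optimizer_beats_random_feasible_candidates(rng):
    """The closed-form (P*, W*) attains a lower objective than 100 random
    B-orthonormalized candidates with the same W-update rule."""
    X1, X2, X3, Y = _toy_problem(rng)
    gammas = (1e-4,) * 3
    model = fit_mvopls(X1, X2, X3, Y, k=2, gammas=gammas)
    d = 3
    X = np.concatenate([X1, X2, X3])
    B = np.zeros((9, 9))
    for s, Xs in enumerate((X1, X2, X3)):
        B[s * d : (s + 1) * d, s * d : (s + 1) * d] = Xs @ Xs.T + gammas[s] * np.eye(d)
    best = _eq2_objective(model.P_star, model.W_star, (X1, X2, X3), Y, gammas, d)
    for _ in range(100):
        P = rng.normal(size=(9, 2))
        # B-orthonormalize the candidate
        M = P.T @ B @ P
        P = P @ np.linalg.inv(linalg.sqrtm(M).real)
        W = np.linalg.solve(P.T @ B @ P, P.T @ (X @ Y.T))
        assert best <= _eq2_objective(P, W, (X1, X2, X3), Y, gammas, d) + 1e-9


def test_default_tikhonov_value():
    from omtapc.apc import DEFAULT_TIKHONOV

    assert DEFAULT_TIKHONOV == 1e-4
    clf = APCClassifier()
    assert clf.gammas == (1e-4, 1e-4, 1e-4)


def test_nonpositive_gamma_rejected(rng):
    X1, X2, X3, Y = _toy_problem(rng)
    with pytest.raises(ValueError):
        fit_mvopls(X1, X2, X3, Y, k=2, gammas=(0.0, 1e-4, 1e-4))


# ---------------------------------------------------------------------------
# label smoothing


def test_label_smoothing_values():
    assert np.allclose(label_smooth(np.array([1.0, 0.0]), 0.1), [0.95, 0.05])
    assert np.allclose(label_smooth(np.array([0.0, 1.0]), 0.0), [0.0, 1.0])
    for eps in (0.0, 0.1, 0.5):
        assert label_smooth(np.array([1.0, 0.0]), eps).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        label_smooth(np.array([1.0, 0.0]), 1.0)
    with pytest.raises(ValueError):
        label_smooth(np.array([0.5, 0.5]), 0.1)


# ---------------------------------------------------------------------------
# cropping


def _tensor_with_labels(labels, intens=None):
    m = labels.shape[0]
    if intens is None:
        intens = np.zeros((2, m, m, m))
    return OMTTensor(intensities=intens, labels=labels.astype(np.uint8),
                     gamma=1.75, provenance={"subject_id": "t"})


def test_crop_single_voxel_bbox():
    labels = np.zeros((12, 12, 12))
    labels[5, 6, 7] = 1
    grid = np.zeros((2, 12, 12, 12))
    grid[:] = np.arange(12)[None, :, None, None]  # intensity = x index
    crop = crop_wt_tensor(_tensor_with_labels(labels, grid), m=8)[0]
    # bounding box [4,6] in x: sampled values stay within it
    assert crop.values.min() == pytest.approx(4.0)
    assert crop.values.max() == pytest.approx(6.0)


def test_crop_clamps_at_borders():
    labels = np.zeros((12, 12, 12))
    labels[0, 0, 0] = 1
    crop = crop_wt_tensor(_tensor_with_labels(labels), m=8)
    assert crop[0].values.shape == (8, 8, 8)


def test_crop_full_extent_equals_resized_tensor(rng):
    labels = np.ones((10, 10, 10))
    grid = rng.normal(size=(2, 10, 10, 10))
    crop = crop_wt_tensor(_tensor_with_labels(labels, grid), m=6)[0]
    from scipy.ndimage import map_coordinates

    axes = [np.linspace(0, 9, 6)] * 3
    mg = np.meshgrid(*axes, indexing="ij")
    expected = map_coordinates(grid[0], np.stack([g.ravel() for g in mg]), order=1).reshape(6, 6, 6)
    assert np.allclose(crop.values, expected)


def test_crop_empty_wt_rejected():
    with pytest.raises(ValueError, match="segmentation|WT"):
        crop_wt_tensor(_tensor_with_labels(np.zeros((10, 10, 10))))


# ---------------------------------------------------------------------------
# preclassification


def test_memorized_exemplars_are_recalled(rng):
    crops0 = {m: _random_tensor(rng, 8) for m in (0, 1)}
    crops1 = {m: TumorTensor(rng.normal(size=(8, 8, 8)) + 1.5) for m in (0, 1)}
    clf = APCClassifier(j=2).fit([crops0, crops1] * 4, [0, 1] * 4)
    assert clf.preclassify(crops1).predicted_class == 1
    assert clf.preclassify(crops0).predicted_class == 0


def test_preclassification_structure(rng):
    subjects = [
        {m: _random_tensor(rng, 8) for m in (0, 1)} for _ in range(6)
    ]
    clf = APCClassifier(j=2).fit(subjects, [0, 1, 0, 1, 0, 1])
    pre = clf.preclassify(subjects[0])
    assert len(pre.per_view) == 6  # 2 modalities x 3 modes
    assert pre.aggregate.sum() == pytest.approx(1.0)
    assert np.all(pre.aggregate >= 0) and np.all(pre.aggregate <= 1)
    assert pre.predicted_class in (0, 1)


def test_dimension_mismatch_reported(rng):
    subjects = [{0: _random_tensor(rng, 8)} for _ in range(4)]
    clf = APCClassifier(j=2).fit(subjects, [0, 1, 0, 1])
    bad = extract_mode_features(_random_tensor(rng, 8), j=3)
    with pytest.raises(ValueError, match="d"):
        preclassify(clf.models, {0: bad})
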