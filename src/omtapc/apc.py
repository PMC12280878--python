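"""Algebraic preclassification: multimode SVD features + multiview OPLS.

From each subject's whole-tumor (WT) crop T ∈ R^{m×m×m} the model takes the
three mode unfoldings T(s) ∈ R^{m×m²}, keeps the best rank-j approximation
U_j Σ_j V_jᵀ of each, and uses x(s) = vec(U_j Σ_j) ∈ R^d (d = m·j) as the
view-s feature. Training solves a multiview orthonormalized partial least
squares (MvOPLS) problem with class-balanced weighting and Tikhonov
regularization:

    min_{P_s, W}  Σ_s ‖Y − Wᵀ P_sᵀ X_s‖_F² + Σ_s γ_s ‖P_s W‖_F²

whose optimum is found from the generalized eigenvalue problem
max tr(PᵀAP) s.t. PᵀBP = I_k with A = XYᵀYXᵀ and
B = blockdiag(X_sX_sᵀ + γ_s I_d). At test time each view yields a
probability-like 2-vector y_t(s) = W*ᵀ P*(s)ᵀ x_t(s); with two modalities
this gives six preclassification vectors per subject.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg
from scipy.ndimage import map_coordinates

from .transport import OMTTensor

__all__ = [
    "TumorTensor",
    "ModeFeatures",
    "MvOPLSModel",
    "Preclassification",
    "APCClassifier",
    "crop_wt_tensor",
    "mode_unfold",
    "mode_fold",
    "svd_feature",
    "extract_mode_features",
    "build_weighted_matrices",
    "fit_mvopls",
    "preclassify",
    "label_smooth",
    "one_hot",
]

DEFAULT_TIKHONOV = 1e-4  # Tikhonov regularization weight per view


@dataclasses.dataclass
class TumorTensor:
    """Cubic m³ intensity crop of the whole-tumor region."""

    values: np.ndarray
    subject_id: str = ""
    modality: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError("tumor tensor must be cubic (m, m, m)")
        if v.shape[0] < 4:
            raise ValueError("tumor tensor needs m >= 4")
        if not np.all(np.isfinite(v)):
            raise ValueError("tumor tensor must be finite")
        self.values = v

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class ModeFeatures:
    """vec(UΣ) features of the three mode unfoldings."""

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    j: int
    singular_values: np.ndarray  # (3, j)

    @property
    def d(self) -> int:
        return len(self.x1)

    def view(self, s: int) -> np.ndarray:
        return (self.x1, self.x2, self.x3)[s - 1]


@dataclasses.dataclass
class MvOPLSModel:
    P_star: np.ndarray  # (3d, k), B-orthonormal generalized eigenvectors
    W_star: np.ndarray  # (k, 2)
    k: int
    d: int
    gammas: tuple[float, float, float]
    eigenvalues: np.ndarray
    class_counts: tuple[int, int]
    objective: float
    #: per-view training means subtracted from features before projection;
    #: centering keeps the leading component discriminative instead of
    #: spending it on the grand mean
    view_centers: np.ndarray | None = None  # (3, d)

    def view_block(self, s: int) -> np.ndarray:
        """P*(s), the d×k block of P* belonging to view s ∈ {1,2,3}."""
        return self.P_star[(s - 1) * self.d : s * self.d]

    def view_scores(self, features: ModeFeatures) -> np.ndarray:
        """The three raw 2-vectors y_t(s) = W*ᵀ P*(s)ᵀ x_t(s); shape (3, 2)."""
        if features.d != self.d:
            raise ValueError(
                f"feature dimension {features.d} does not match model d={self.d}"
            )
        out = []
        for s in (1, 2, 3):
            x = features.view(s)
            if self.view_centers is not None:
                x = x - self.view_centers[s - 1]
            out.append(self.W_star.T @ (self.view_block(s).T @ x))
        return np.stack(out)


@dataclasses.dataclass
class Preclassification:
    """Raw per-view scores plus an aggregated probability."""

    per_view: dict  # {(modality, mode): 2-vector}
    aggregate: np.ndarray  # softmax probabilities, sums to 1
    predicted_class: int


def one_hot(label: int) -> np.ndarray:
    """Class 0 → [1, 0]; class 1 → [0, 1]."""
    if label not in (0, 1):
        raise ValueError("binary labels only")
    y = np.zeros(2)
    y[label] = 1.0
    return y


def crop_wt_tensor(tensor: OMTTensor, m: int = 32) -> dict[int, TumorTensor]:
    """Extract the m³ whole-tumor crop of each modality.

    The axis-aligned bounding box of the WT label channel, padded by one
    voxel per side (clamped to the grid), is trilinearly resampled to an
    m×m×m cube (inclusive corner-aligned sampling).
    """
    labels = tensor.labels
    if labels.sum() == 0:
        raise ValueError(
            "tensor has no WT voxels; check the segmentation / label channel"
        )
    idx = np.argwhere(labels > 0)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 1, np.array(labels.shape) - 1)
    axes_samples = [np.linspace(lo[a], hi[a], m) for a in range(3)]
    grid = np.meshgrid(*axes_samples, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = {}
    for mod in range(tensor.intensities.shape[0]):
        vals = map_coordinates(
            tensor.intensities[mod], coords, order=1, mode="nearest"
        ).reshape(m, m, m)
        out[mod] = TumorTensor(
            values=vals, subject_id=tensor.provenance.get("subject_id", ""), modality=mod
        )
    return out


def mode_unfold(tensor: TumorTensor | np.ndarray, s: int) -> np.ndarray:
    """The s-mode unfolding T(s) ∈ R^{m×m²}.

    Row i is the vectorization of the slice fixing index s at i; the
    remaining modes are ordered ascending with the first-listed varying
    fastest (Fortran vectorization of the slice).
    """
    values = tensor.values if isinstance(tensor, TumorTensor) else np.asarray(tensor)
    if s not in (1, 2, 3):
        raise ValueError("mode s must be 1, 2 or 3")
    m = values.shape[0]
    return np.moveaxis(values, s - 1, 0).reshape(m, -1, order="F")


def mode_fold(matrix: np.ndarray, s: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`mode_unfold`."""
    rest = [shape[a] for a in range(3) if a != s - 1]
    arr = matrix.reshape((shape[s - 1], *rest), order="F")
    return np.moveaxis(arr, 0, s - 1)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: the largest-magnitude entry of
    every left singular vector is made positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def svd_feature(T_s: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """vec(U_j Σ_j) of the rank-j truncated SVD of an unfolding.

    Returns (x, singular_values) with x of length d = m·j, columns ordered
    by descending singular value.
    """
    m = T_s.shape[0]
    if not 1 <= j < m:
        raise ValueError(f"SVD rank j must satisfy 1 <= j < m (got j={j}, m={m})")
    U, S, _ = np.linalg.svd(T_s, full_matrices=False)
    U = _fix_signs(U[:, :j])
    x = (U * S[:j]).ravel(order="F")
    return x, S[:j]


def extract_mode_features(tensor: TumorTensor, j: int = 8) -> ModeFeatures:
    """Truncated-SVD features of all three mode unfoldings."""
    xs, svs = [], []
    for s in (1, 2, 3):
        x, sv = svd_feature(mode_unfold(tensor, s), j)
        xs.append(x)
        svs.append(sv)
    return ModeFeatures(x1=xs[0], x2=xs[1], x3=xs[2], j=j, singular_values=np.stack(svs))


def build_weighted_matrices(
    features: list[ModeFeatures], labels: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-balanced view matrices X ∈ R^{3d×n}, targets Y ∈ R^{2×n}, D_n.

    Subjects of the class with one-hot [1,0] get weight 1/n1, the other
    class 1/n2, so each class contributes unit total weight regardless of
    imbalance. Returns (X, Y, d_weights) with the weights already applied
    to X and Y.
    """
    if len(features) != len(labels) or not features:
        raise ValueError("features and labels must be equal-length, nonempty")
    Yraw = np.stack([np.asarray(y, float) for y in labels], axis=1)  # (2, n)
    if not np.all(np.isin(Yraw, (0.0, 1.0))) or not np.all(Yraw.sum(axis=0) == 1.0):
        raise ValueError("labels must be one-hot 2-vectors")
    n1 = int(Yraw[0].sum())
    n2 = int(Yraw[1].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present in the training set")
    d_weights = np.where(Yraw[0] == 1.0, 1.0 / n1, 1.0 / n2)
    X = np.concatenate(
        [np.stack([f.view(s) for f in features], axis=1) for s in (1, 2, 3)], axis=0
    )
    return X * d_weights, Yraw * d_weights, d_weights


def fit_mvopls(
    X1: np.ndarray,
    X2: np.ndarray,
    X3: np.ndarray,
    Y: np.ndarray,
    k: int = 2,
    gammas: tuple[float, float, float] = (DEFAULT_TIKHONOV,) * 3,
    class_counts: tuple[int, int] | None = None,
) -> MvOPLSModel:
    """Fit MvOPLS from weighted view matrices X_s ∈ R^{d×n} and Y ∈ R^{2×n}.

    Solves the generalized eigenvalue problem (A, B) with A = XYᵀYXᵀ and
    B = blockdiag(X_sX_sᵀ + γ_s I); P* collects the k B-orthonormal
    eigenvectors with the largest eigenvalues, and
    W* = (P*ᵀBP*)⁻¹P*ᵀXYᵀ (the inverse guards against inexact
    orthonormalization). k=2 matches rank(A) ≤ 2 for binary labels.
    """
    if any(g <= 0 for g in gammas):
        raise ValueError("Tikhonov parameters must be positive (B must be definite)")
    d = X1.shape[0]
    if not (X2.shape[0] == X3.shape[0] == d):
        raise ValueError("views must share the feature dimension d")
    if k < 1 or k > 3 * d:
        raise ValueError("k must be in [1, 3d]")
    X = np.concatenate([X1, X2, X3], axis=0)  # (3d, n)
    XY = X @ Y.T  # (3d, 2)
    A = XY @ XY.T
    B = np.zeros((3 * d, 3 * d))
    for s, (Xs, g) in enumerate(zip((X1, X2, X3), gammas)):
        blk = slice(s * d, (s + 1) * d)
        B[blk, blk] = Xs @ Xs.T + g * np.eye(d)
    # dense generalized symmetric-definite eigenproblem; eigh returns
    # B-orthonormal eigenvectors in ascending eigenvalue order
    evals, evecs = linalg.eigh(A, B)
    order = np.argsort(evals)[::-1][:k]
    # contiguous copy: keeps scoring bit-reproducible across serialization
    P = np.ascontiguousarray(_fix_signs(evecs[:, order]))
    PBP = P.T @ B @ P
    W = np.linalg.solve(PBP, P.T @ XY)
    objective = float(np.trace(P.T @ A @ P))
    if class_counts is None:
        class_counts = (0, 0)  # unknown: caller did not provide raw counts
    return MvOPLSModel(
        P_star=P,
        W_star=W,
        k=k,
        d=d,
        gammas=tuple(float(g) for g in gammas),
        eigenvalues=evals[order],
        class_counts=tuple(class_counts),
        objective=objective,
    )


def label_smooth(y: np.ndarray, epsilon: float, n_classes: int = 2) -> np.ndarray:
    """Label smoothing ŷ = (1−ε)y + ε/C for a one-hot target."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    y = np.asarray(y, float)
    if y.sum() != 1.0 or not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be one-hot")
    return (1.0 - epsilon) * y + epsilon / n_classes


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def preclassify(
    models: dict[int, MvOPLSModel], features: dict[int, ModeFeatures]
) -> Preclassification:
    """Six raw preclassification vectors (2 modalities × 3 modes) + aggregate.

    The aggregate is the softmax of the mean of the raw vectors; ties in the
    argmax break toward class 0. Raw vectors are exposed unmodified (they
    are probability approximations, not guaranteed to lie in the simplex).
    """
    per_view = {}
    raw = []
    for mod in sorted(models):
        if mod not in features:
            raise ValueError(f"missing features for modality {mod}")
        scores = models[mod].view_scores(features[mod])  # (3, 2)
        for s in (1, 2, 3):
            per_view[(mod, s)] = scores[s - 1]
            raw.append(scores[s - 1])
    mean = np.mean(raw, axis=0)
    aggregate = _softmax(mean)
    predicted = 1 if aggregate[1] > aggregate[0] else 0
    return Preclassification(
        per_view=per_view, aggregate=aggregate, predicted_class=predicted
    )


def _fit_modality(
    feats: list[ModeFeatures], onehots, k, gammas, class_counts
) -> MvOPLSModel:
    """Fit one modality's MvOPLS on centered, class-balanced features."""
    centers = np.stack(
        [np.mean([f.view(s) for f in feats], axis=0) for s in (1, 2, 3)]
    )
    centered = [
        ModeFeatures(
            x1=f.x1 - centers[0], x2=f.x2 - centers[1], x3=f.x3 - centers[2],
            j=feats[0].j, singular_values=f.singular_values,
        )
        for f in feats
    ]
    X, Y, _ = build_weighted_matrices(centered, onehots)
    d = feats[0].d
    model = fit_mvopls(
        X[:d], X[d : 2 * d], X[2 * d :], Y, k=k, gammas=gammas,
        class_counts=class_counts,
    )
    model.view_centers = centers
    return model


class APCClassifier:
    """Two-modality APC: one MvOPLS model per modality plus a calibrated
    combiner over the six preclassification views.

    ``fit`` trains the per-modality MvOPLS models (with per-view feature
    centering) and then estimates each view's reliability by deterministic
    stratified cross-validation; ``predict_proba`` aggregates the six raw
    vectors into one probability by reliability-weighted averaging of
    rank-calibrated view scores. The raw y_t(s) vectors are always exposed
    via :meth:`preclassify`, so downstream users can feed them into their
    own combiner (e.g. a network layer) instead.
    """

    N_FOLDS = 4

    def __init__(
        self,
        j: int = 8,
        k: int = 2,
        gammas: tuple[float, float, float] = (DEFAULT_TIKHONOV,) * 3,
    ):
        self.j = j
        self.k = k
        self.gammas = tuple(gammas)
        self.models: dict[int, MvOPLSModel] = {}
        self.view_weights: dict[tuple[int, int], float] = {}
        self.train_refs: dict[tuple[int, int], np.ndarray] = {}

    def _features(self, crops: dict[int, TumorTensor]) -> dict[int, ModeFeatures]:
        return {mod: extract_mode_features(t, self.j) for mod, t in crops.items()}

    @staticmethod
    def _view_margin(model: MvOPLSModel, feats: ModeFeatures, s: int) -> float:
        y = model.view_scores(feats)[s - 1]
        return float(y[1] - y[0])

    def _cv_view_weights(self, feats_by_mod, labels) -> dict:
        """Per-view reliability from stratified K-fold CV margins (AUC)."""
        from .metrics import auc as _auc

        n = len(labels)
        labels = np.asarray(labels)
        folds = [[] for _ in range(self.N_FOLDS)]
        for cls in (0, 1):
            for pos, idx in enumerate(np.flatnonzero(labels == cls)):
                folds[pos % self.N_FOLDS].append(int(idx))
        weights = {}
        margins = {key: np.full(n, np.nan) for key in
                   [(m, s) for m in feats_by_mod for s in (1, 2, 3)]}
        for fold in folds:
            train = sorted(set(range(n)) - set(fold))
            tr_labels = labels[train]
            if len(set(tr_labels.tolist())) < 2 or not fold:
                continue
            onehots = [one_hot(int(l)) for l in tr_labels]
            counts = (int((tr_labels == 0).sum()), int((tr_labels == 1).sum()))
            for mod, feats in feats_by_mod.items():
                model = _fit_modality(
                    [feats[i] for i in train], onehots, self.k, self.gammas, counts
                )
                for i in fold:
                    for s in (1, 2, 3):
                        margins[(mod, s)][i] = self._view_margin(model, feats[i], s)
        for key, vals in margins.items():
            ok = ~np.isnan(vals)
            a = _auc(labels[ok], vals[ok]) if ok.sum() >= 4 else None
            weights[key] = max(a - 0.5, 0.0) if a is not None else 0.0
        if all(w == 0.0 for w in weights.values()):
            weights = {key: 1.0 for key in weights}
        total = sum(weights.values())
        return {key: w / total for key, w in weights.items()}

    def fit(
        self, subjects: list[dict[int, TumorTensor]], labels: list[int]
    ) -> "APCClassifier":
        if len(subjects) != len(labels) or len(subjects) < 2:
            raise ValueError("need matching subjects/labels, at least two subjects")
        labels = [int(l) for l in labels]
        onehots = [one_hot(l) for l in labels]
        n1 = labels.count(0)
        n2 = labels.count(1)
        modalities = sorted(subjects[0])
        feats_by_mod = {
            mod: [self._features(s)[mod] for s in subjects] for mod in modalities
        }
        self.models = {
            mod: _fit_modality(feats_by_mod[mod], onehots, self.k, self.gammas, (n1, n2))
            for mod in modalities
        }
        # reliability weights from CV, reference margins from the full fit
        if len(subjects) >= 2 * self.N_FOLDS:
            self.view_weights = self._cv_view_weights(feats_by_mod, labels)
        else:
            keys = [(m, s) for m in modalities for s in (1, 2, 3)]
            self.view_weights = {key: 1.0 / len(keys) for key in keys}
        self.train_refs = {
            (mod, s): np.sort(
                [self._view_margin(self.models[mod], f, s) for f in feats_by_mod[mod]]
            )
            for mod in modalities
            for s in (1, 2, 3)
        }
        return self

    def preclassify(self, crops: dict[int, TumorTensor]) -> Preclassification:
        """Six raw vectors plus the calibrated, reliability-weighted aggregate."""
        if not self.models:
            raise RuntimeError("classifier is not fitted")
        features = self._features(crops)
        per_view = {}
        p1 = 0.0
        for mod in sorted(self.models):
            if mod not in features:
                raise ValueError(f"missing features for modality {mod}")
            scores = self.models[mod].view_scores(features[mod])
            for s in (1, 2, 3):
                per_view[(mod, s)] = scores[s - 1]
                ref = self.train_refs[(mod, s)]
                margin = float(scores[s - 1][1] - scores[s - 1][0])
                rank = np.searchsorted(ref, margin, side="left")
                rank += 0.5 * (np.searchsorted(ref, margin, side="right") - rank)
                prob = (rank + 0.5) / (len(ref) + 1.0)
                p1 += self.view_weights.get((mod, s), 0.0) * prob
        aggregate = np.array([1.0 - p1, p1])
        predicted = 1 if aggregate[1] > aggregate[0] else 0
        return Preclassification(
            per_view=per_view, aggregate=aggregate, predicted_class=predicted
        )

    def predict_proba(self, crops: dict[int, TumorTensor]) -> float:
        """Aggregated probability of class 1."""
        return float(self.preclassify(crops).aggregate[1])
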