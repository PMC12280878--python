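"""Classification and segmentation evaluation metrics.

Classification metrics mirror standard clinical reporting: AUC (Mann–
Whitney formulation with ties counted half), accuracy, sensitivity,
specificity, PPV, NPV and F1 from a thresholded confusion table. Undefined
ratios (zero denominators) are reported as None, never silently as 0.
Segmentation metrics are plain volumetric Dice and HD95 (95th percentile of
the pooled symmetric surface distances, in mm); per-lesion matching is out
of scope and deliberately not implemented.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "auc",
    "auc_ci",
    "confusion_metrics",
    "dice",
    "hd95",
]


@dataclasses.dataclass
class MetricsReport:
    n: int
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None
    acc: float | None
    sens: float | None
    spec: float | None
    ppv: float | None
    npv: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def auc(labels, scores) -> float | None:
    """Area under the ROC curve via the Mann–Whitney U statistic.

    Ties between a positive and a negative score count 1/2. Returns None
    when only one class is present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks over ties -> ties count 1/2
    r_pos = ranks[y == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_ci(
    labels, scores, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float | None, float | None]:
    """Percentile bootstrap confidence interval for the AUC (fixed seed)."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        a = auc(y[idx], s[idx])
        if a is not None:
            vals.append(a)
    if not vals:
        return None, None
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else float(num / den)


def confusion_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold scores and derive the confusion-table metrics."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, float)
    if len(y) == 0:
        raise ValueError("empty input")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)
    sens = _safe_div(tp, tp + fn)
    ppv = _safe_div(tp, tp + fp)
    f1 = (
        None
        if ppv is None or sens is None or (ppv + sens) == 0
        else 2.0 * ppv * sens / (ppv + sens)
    )
    return MetricsReport(
        n=n,
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=auc(y, s),
        acc=_safe_div(tp + tn, n),
        sens=sens,
        spec=_safe_div(tn, tn + fp),
        ppv=ppv,
        npv=_safe_div(tn, tn + fn),
        f1=f1,
    )


def dice(mask_a, mask_b) -> float:
    """Volumetric Dice overlap 2|A∩B| / (|A|+|B|); both-empty → 1.0."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def hd95(mask_a, mask_b, spacing=(1.0, 1.0, 1.0)) -> float | None:
    """95th percentile of the pooled symmetric surface distances, in mm.

    Returns None when either mask is empty. Symmetric in its arguments by
    construction (distances A→B and B→A are pooled before the percentile).
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        return None
    sa, sb = _surface(a), _surface(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    pooled = np.concatenate([dist_to_b[sa], dist_to_a[sb]])
    return float(np.percentile(pooled, 95))
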