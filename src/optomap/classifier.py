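"""One-dimensional soft-margin max-margin classifier on the I_h slope.

The decision boundary is the exact minimizer of the linear-kernel
soft-margin objective

    J(w, b) = ½ w² + C · Σ_classes (1/n_c) Σ_{i in c} max(0, 1 − y_i (w x_i + b))

with per-class mean hinge loss, i.e. a uniform class prior regardless of
class counts. In one dimension the profile g(w) = min_b J(w, b) is convex
and min_b is attained at a hinge breakpoint, so the solver evaluates the
breakpoints exactly and ternary-searches w — no generic SVM library is
involved. For separable data at large C this reduces to the hard-margin
boundary: the midpoint of the innermost opposite-class pair.

Cross-validation follows the study protocol: stratified tenfold splits,
the whole tenfold process repeated 20 times with fresh random divisions,
and a 1000-permutation shuffled-label null whose empirical 2.5–97.5
percentile interval is the chance band.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LabeledSlopes",
    "ClassifierModel",
    "CVResult",
    "fit",
    "predict",
    "cross_validate",
    "shuffled_null",
    "prediction_accuracy",
    "hinge_objective",
]


@dataclass(frozen=True)
class LabeledSlopes:
    """I_h slopes (pA/s) with two-class labels."""

    slopes: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "slopes",
                           np.asarray(self.slopes, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if self.slopes.shape != self.labels.shape or self.slopes.ndim != 1:
            raise ValueError("slopes and labels must be equal-length 1-D")

    @property
    def classes(self) -> tuple:
        return tuple(sorted(set(self.labels.tolist())))

    def subset(self, idx) -> "LabeledSlopes":
        return LabeledSlopes(self.slopes[idx], self.labels[idx])


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted 1-D boundary: predict class_above iff slope >= boundary."""

    boundary: float              # pA/s
    class_above: str
    class_below: str
    margin: float                # pA/s, boundary-to-support distance (1/|w|)
    regularization_c: float
    training_counts: dict
    degenerate: bool = False

    def orientation(self) -> str:
        return self.class_above


@dataclass(frozen=True)
class CVResult:
    per_repeat_accuracy: np.ndarray     # one per repeat (mean over folds)
    mean_accuracy: float
    null_accuracies: np.ndarray | None = None
    null_95_interval: tuple[float, float] | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Exact 1-D solver
# ---------------------------------------------------------------------------

def hinge_objective(w: float, b: float, x: np.ndarray, y: np.ndarray,
                    c: float) -> float:
    """Soft-margin objective with per-class mean hinge (uniform prior)."""
    hinge = np.maximum(0.0, 1.0 - y * (w * x + b))
    loss = 0.0
    for cls in (-1.0, 1.0):
        mask = y == cls
        if np.any(mask):
            loss += hinge[mask].mean()
    return 0.5 * w * w + c * loss


def _min_over_b(w: float, x: np.ndarray, y: np.ndarray, c: float,
                class_w: np.ndarray) -> tuple[float, float]:
    """Exact min_b J(w, b): the hinge loss is convex piecewise linear in b
    with breakpoints b_i = y_i − w·x_i, so the minimum sits where the
    subgradient changes sign; found by a prefix-sum sweep in O(n log n).

    For y=+1 the i-th hinge is active for b < b_i (slope −cw_i), for y=−1
    it is active for b > b_i (slope +cw_i).
    """
    b_cand = y - w * x
    order = np.argsort(b_cand, kind="stable")
    b_sorted = b_cand[order]
    w_sorted = class_w[order]
    pos = y[order] > 0
    # slope of the loss just left of breakpoint k:
    #   −(sum of +1 weights with b_i >= b_k) + (sum of −1 weights with b_i < b_k)
    pos_tail = np.cumsum((w_sorted * pos)[::-1])[::-1]          # b_i >= b_k
    neg_head = np.concatenate(([0.0], np.cumsum(w_sorted * ~pos)[:-1]))
    slope_left = -pos_tail + neg_head
    # J decreases while the interval slope is negative; the minimum is the
    # left endpoint of the first interval with slope >= 0
    k = int(np.searchsorted(slope_left, 0.0, side="left"))
    b_best = float(b_sorted[np.clip(k - 1, 0, b_sorted.size - 1)])
    marg = 1.0 - y * (w * x + b_best)
    loss = float((class_w * np.maximum(0.0, marg)).sum())
    return 0.5 * w * w + c * loss, b_best


def fit(data: LabeledSlopes, C: float = 1.0) -> ClassifierModel:
    """Exact 1-D soft-margin fit with equal class weighting.

    Raises on single-class data or fewer than two points per class; data
    where the two classes are indistinguishable (zero between-class gap
    everywhere) yield a zero-margin model flagged ``degenerate``.
    """
    classes = data.classes
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    lo_cls, hi_cls = classes
    n_lo = int(np.sum(data.labels == lo_cls))
    n_hi = int(np.sum(data.labels == hi_cls))
    if min(n_lo, n_hi) < 2:
        raise ValueError("need at least two points per class")
    mean_lo = data.slopes[data.labels == lo_cls].mean()
    mean_hi = data.slopes[data.labels == hi_cls].mean()
    if mean_hi < mean_lo:
        lo_cls, hi_cls = hi_cls, lo_cls

    x = data.slopes
    y = np.where(data.labels == hi_cls, 1.0, -1.0)
    class_w = np.where(y > 0, 1.0 / np.sum(y > 0), 1.0 / np.sum(y < 0))

    x_above = x[y > 0]
    x_below = x[y < 0]
    if np.ptp(x) == 0:
        # all slopes identical: no boundary separates anything
        return ClassifierModel(
            boundary=float(x[0]), class_above=hi_cls, class_below=lo_cls,
            margin=0.0, regularization_c=C,
            training_counts={lo_cls: n_lo, hi_cls: n_hi}, degenerate=True)

    # candidate hard-margin slope from every opposite-class pair
    gaps = x_above[:, None] - x_below[None, :]
    pos = gaps[gaps > 0]
    w_hi = 2.0 / pos.min() if pos.size else 0.0
    w_max = max(w_hi, 4.0 / np.ptp(x)) * 4.0
    w_lo = 1e-12

    def g(w: float) -> float:
        return _min_over_b(w, x, y, C, class_w)[0]

    # ternary search on the convex profile g(w)
    a, b_ = w_lo, w_max
    for _ in range(80):
        m1 = a + (b_ - a) / 3.0
        m2 = b_ - (b_ - a) / 3.0
        if g(m1) <= g(m2):
            b_ = m2
        else:
            a = m1
    w_best = 0.5 * (a + b_)
    # polish against the exact hard-margin candidate
    if w_hi > 0 and g(w_hi) < g(w_best):
        w_best = w_hi
    obj, b_best = _min_over_b(w_best, x, y, C, class_w)

    if w_best <= 2e-12:
        return ClassifierModel(
            boundary=float(np.median(x)), class_above=hi_cls,
            class_below=lo_cls, margin=0.0, regularization_c=C,
            training_counts={lo_cls: n_lo, hi_cls: n_hi}, degenerate=True)
    return ClassifierModel(
        boundary=-b_best / w_best,
        class_above=hi_cls,
        class_below=lo_cls,
        margin=1.0 / w_best,
        regularization_c=C,
        training_counts={lo_cls: n_lo, hi_cls: n_hi},
    )


def predict(model: ClassifierModel, slopes) -> np.ndarray:
    """Threshold slopes at the boundary; ties go to the class above."""
    slopes = np.asarray(slopes, dtype=float)
    return np.where(slopes >= model.boundary, model.class_above,
                    model.class_below)


def prediction_accuracy(pred, truth) -> float:
    """Fraction of correct predictions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("predictions and truth must be equal-length, nonempty")
    return float(np.mean(pred == truth))


# ---------------------------------------------------------------------------
# Cross-validation and permutation null
# ---------------------------------------------------------------------------

def _one_cv_pass(data: LabeledSlopes, k: int, C: float,
                 rng: np.random.Generator, max_redraws: int = 10) -> float:
    """One stratified k-fold pass; returns the mean fold accuracy."""
    for _attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        accs = []
        ok = True
        for train_idx, test_idx in skf.split(data.slopes, data.labels):
            train = data.subset(train_idx)
            if len(set(train.labels.tolist())) < 2 or any(
                    np.sum(train.labels == c) < 2 for c in train.classes):
                ok = False
                break
            model = fit(train, C=C)
            accs.append(prediction_accuracy(
                predict(model, data.slopes[test_idx]),
                data.labels[test_idx]))
        if ok:
            return float(np.mean(accs))
    raise RuntimeError("could not draw folds with both classes in training")


def cross_validate(data: LabeledSlopes, k: int = 10, repeats: int = 20,
                   C: float = 1.0, seed: int | None = None) -> CVResult:
    """Stratified k-fold accuracy, the whole pass repeated with fresh
    random divisions; reproducible under ``seed``."""
    if data.slopes.size < k:
        raise ValueError("need at least k points")
    rng = np.random.default_rng(seed)
    per_repeat = np.array([_one_cv_pass(data, k, C, rng)
                           for _ in range(repeats)])
    return CVResult(per_repeat_accuracy=per_repeat,
                    mean_accuracy=float(per_repeat.mean()),
                    seed=seed)


def shuffled_null(data: LabeledSlopes, n_shuffles: int = 1000, k: int = 10,
                  repeats: int = 1, C: float = 1.0,
                  seed: int | None = None) -> CVResult:
    """Shuffled-label null distribution of CV accuracy.

    Labels are permuted per instance, the CV protocol re-run, and the
    empirical 2.5–97.5 percentile interval returned as the chance band.
    """
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = LabeledSlopes(data.slopes,
                             data.labels[rng.permutation(data.labels.size)])
        null[s] = np.mean([_one_cv_pass(perm, k, C, rng)
                           for _ in range(repeats)])
    low, high = np.percentile(null, [2.5, 97.5])
    return CVResult(per_repeat_accuracy=null, mean_accuracy=float(null.mean()),
                    null_accuracies=null,
                    null_95_interval=(float(low), float(high)), seed=seed)
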