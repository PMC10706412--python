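"""Chemometrics: PCA, SVM classification, random-search tuning, validation.

The fingerprint matrix (n samples x 18 colour-change features) is
reduced by centred PCA, and a soft-margin SVM (one-vs-one multiclass)
is trained on the leading principal-component scores. Hyperparameters
— kernel family, Gaussian kernel scale, polynomial order, box
constraint C, and whether to standardise predictors — are tuned by
random search against a stratified k-fold cross-validation error, and
the tuned configuration is assessed by repeated stratified 70/30
calibration/prediction splits summarised as confusion matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import CSAError
from .scheme import CLASS_ORDER

__all__ = [
    "PCAModel",
    "fit_pca",
    "select_n_components",
    "HyperparamConfig",
    "kernel_value",
    "build_svm",
    "train_svm",
    "cv_objective",
    "SearchTrace",
    "random_search",
    "calibration_size",
    "stratified_split",
    "SplitEvaluation",
    "repeated_split_evaluate",
    "ConfusionMatrix",
    "confusion_stats",
]

#: Hyperparameter search range for kernel scale and box constraint.
SEARCH_RANGE = (1e-3, 1e3)

KERNELS = ("gaussian", "linear", "polynomial")
POLY_ORDERS = (2, 3, 4)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    """Centred principal-component model of a feature matrix.

    ``loadings`` is (p, m) with orthonormal columns; ``explained_ratio``
    holds the fraction of total variance per component (nonincreasing).
    The sign convention makes the largest-magnitude loading entry of
    each component positive.
    """

    means: np.ndarray
    loadings: np.ndarray
    explained_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray, n_components: Optional[int] = None) -> np.ndarray:
        m = self.n_components if n_components is None else n_components
        X = np.asarray(X, dtype=float)
        return (X - self.means) @ self.loadings[:, :m]

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        m = scores.shape[1]
        return scores @ self.loadings[:, :m].T + self.means


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit centred (unscaled) PCA to an n x p feature matrix.

    Components are eigenvectors of the sample covariance; no variance
    scaling is applied because predictor standardisation is a separate,
    searched SVM hyperparameter.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix has no principal components")
    pca = _SKPCA(n_components=None, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        means=pca.mean_.copy(),
        loadings=loadings,
        explained_ratio=pca.explained_variance_ratio_.copy(),
    )


def select_n_components(model: PCAModel, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches
    ``threshold`` (default 95%)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(model.explained_ratio)
    hit = np.flatnonzero(cum >= threshold - 1e-12)
    if len(hit) == 0:
        raise ValueError(
            f"model explains only {cum[-1]:.4f} of variance, below threshold {threshold}"
        )
    return int(hit[0]) + 1


# ---------------------------------------------------------------------------
# SVM configuration and kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperparamConfig:
    """One SVM configuration drawn by the search.

    kernel_scale s enters the Gaussian kernel exp(-||u-v||^2 / s^2) and
    applies only there; poly_order applies only to the polynomial kernel
    (1 + u.v)^d. box_constraint is the soft-margin penalty cap C.
    """

    kernel: str
    box_constraint: float
    kernel_scale: Optional[float] = None
    poly_order: Optional[int] = None
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        if self.kernel == "gaussian":
            if self.kernel_scale is None or self.kernel_scale <= 0:
                raise ValueError("gaussian kernel requires a positive kernel_scale")
        if self.kernel == "polynomial" and self.poly_order not in POLY_ORDERS:
            raise ValueError(f"poly_order must be one of {POLY_ORDERS}")

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "box_constraint": self.box_constraint,
            "kernel_scale": self.kernel_scale,
            "poly_order": self.poly_order,
            "standardize": self.standardize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparamConfig":
        return cls(
            kernel=d["kernel"],
            box_constraint=d["box_constraint"],
            kernel_scale=d.get("kernel_scale"),
            poly_order=d.get("poly_order"),
            standardize=bool(d.get("standardize", False)),
        )


def kernel_value(u: np.ndarray, v: np.ndarray, config: HyperparamConfig) -> float:
    """Evaluate the configured kernel on a pair of vectors.

    linear: u.v; polynomial order d: (1 + u.v)^d; gaussian:
    exp(-||u - v||^2 / s^2) with s = kernel_scale.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if config.kernel == "linear":
        return float(u @ v)
    if config.kernel == "polynomial":
        return float((1.0 + u @ v) ** config.poly_order)
    s = config.kernel_scale
    if s is None or s <= 0:
        raise ValueError("gaussian kernel requires a positive kernel_scale")
    return float(np.exp(-float(np.sum((u - v) ** 2)) / s**2))


def build_svm(config: HyperparamConfig) -> Pipeline:
    """sklearn pipeline realising a configuration (optional standardiser +
    one-vs-one soft-margin SVC).

    A zero-variance predictor under standardisation gets scale 1 (the
    StandardScaler convention), not an error.
    """
    if config.kernel == "gaussian":
        svc = SVC(kernel="rbf", gamma=1.0 / config.kernel_scale**2, C=config.box_constraint)
    elif config.kernel == "linear":
        svc = SVC(kernel="linear", C=config.box_constraint)
    else:
        svc = SVC(
            kernel="poly", degree=config.poly_order, gamma=1.0, coef0=1.0,
            C=config.box_constraint,
        )
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", svc))
    return Pipeline(steps)


def train_svm(X: np.ndarray, y: Sequence, config: HyperparamConfig) -> Pipeline:
    """Fit the configured SVM on training scores X and labels y."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train a classifier")
    clf = build_svm(config)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


# ---------------------------------------------------------------------------
# Cross-validation objective
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign samples to folds by per-class shuffled round-robin dealing.

    Valid for classes smaller than ``n_folds`` (each fold then simply
    lacks that class in its test part); a rotating offset keeps fold
    sizes balanced across classes. Deterministic given the generator.
    """
    folds = np.empty(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (offset + j) % n_folds
        offset += len(idx)
    return folds


def cv_objective(
    X: np.ndarray,
    y: Sequence,
    config: HyperparamConfig,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Stratified k-fold misclassification fraction for one configuration.

    Deterministic given ``seed``. Folds are stratified by round-robin
    dealing within each class, which remains well defined when class
    counts are below the fold count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds sample count {n}")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(y, folds, rng)
    errors = 0
    for f in range(folds):
        test = assign == f
        if not test.any():
            continue
        train = ~test
        clf = train_svm(X[train], y[train], config)
        pred = clf.predict(X[test])
        errors += int((pred != y[test]).sum())
    return errors / n


# ---------------------------------------------------------------------------
# Random search
# ---------------------------------------------------------------------------

@dataclass
class SearchTrace:
    """Ordered record of a random search: one (config, CV error) pair per
    function evaluation."""

    evaluations: list = field(default_factory=list)

    @property
    def objectives(self) -> np.ndarray:
        return np.array([obj for _, obj in self.evaluations], dtype=float)

    @property
    def min_observed(self) -> np.ndarray:
        """Running minimum of the objective — the tuning curve."""
        return np.minimum.accumulate(self.objectives)

    @property
    def best_index(self) -> int:
        obj = self.objectives
        return int(np.argmin(obj))  # first-found on ties

    @property
    def best(self) -> tuple[HyperparamConfig, float]:
        i = self.best_index
        return self.evaluations[i]


def _draw_config(rng: np.random.Generator) -> HyperparamConfig:
    lo, hi = np.log10(SEARCH_RANGE[0]), np.log10(SEARCH_RANGE[1])
    kernel = KERNELS[rng.integers(len(KERNELS))]
    poly_order = int(POLY_ORDERS[rng.integers(len(POLY_ORDERS))])
    kernel_scale = float(10.0 ** rng.uniform(lo, hi))
    box_constraint = float(10.0 ** rng.uniform(lo, hi))
    standardize = bool(rng.integers(2))
    return HyperparamConfig(
        kernel=kernel,
        box_constraint=box_constraint,
        kernel_scale=kernel_scale if kernel == "gaussian" else None,
        poly_order=poly_order if kernel == "polynomial" else None,
        standardize=standardize,
    )


def random_search(
    X: np.ndarray,
    y: Sequence,
    n_iter: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> tuple[SearchTrace, HyperparamConfig]:
    """Random-search SVM tuning against the stratified CV error.

    Each evaluation draws a kernel uniformly from {gaussian, linear,
    polynomial}, a polynomial order uniformly from {2, 3, 4} when
    relevant, kernel scale and box constraint log-uniformly on
    [1e-3, 1e3], and the standardisation flag uniformly. The same CV
    fold seed is reused across evaluations so configurations compete on
    identical folds. Returns the full trace and the first-found argmin.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))
    trace = SearchTrace()
    for _ in range(n_iter):
        config = _draw_config(rng)
        obj = cv_objective(X, y, config, folds=folds, seed=cv_seed)
        trace.evaluations.append((config, obj))
    return trace, trace.best[0]


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------

def calibration_size(n: int, train_frac: float = 0.7) -> int:
    """Calibration-set size: round-half-up of train_frac * n
    (104 samples at 70% -> 73 calibration / 31 prediction)."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    return int(math.floor(train_frac * n + 0.5))


def stratified_split(
    y: np.ndarray, n_cal: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified calibration/prediction index split of exact size ``n_cal``.

    Per-class allocations follow proportional rounding (largest
    remainder), with every class guaranteed at least one calibration
    sample; the prediction part may lack a class when counts are small.
    Returns (calibration_idx, prediction_idx).
    """
    y = np.asarray(y)
    n = len(y)
    if not 0 < n_cal < n:
        raise ValueError("n_cal must lie strictly between 0 and n")
    classes, counts = np.unique(y, return_counts=True)
    if n_cal < len(classes):
        raise ValueError("calibration set smaller than the number of classes")
    exact = n_cal * counts / n
    alloc = np.floor(exact).astype(int)
    alloc = np.maximum(alloc, 1)
    # distribute the remainder by largest fractional part, then trim any
    # overshoot from the most-allocated classes that can spare a sample
    order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    i = 0
    while alloc.sum() < n_cal:
        c = order[i % len(classes)]
        if alloc[c] < counts[c]:
            alloc[c] += 1
        i += 1
    while alloc.sum() > n_cal:
        c = int(np.argmax(alloc))
        if alloc[c] > 1:
            alloc[c] -= 1
    cal, pred = [], []
    for c, cls in enumerate(classes):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        cal.extend(idx[: alloc[c]])
        pred.extend(idx[alloc[c] :])
    return np.sort(np.array(cal, int)), np.sort(np.array(pred, int))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted class,
    in a fixed class order."""

    class_order: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "class_order", tuple(self.class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_stats(cm: ConfusionMatrix) -> dict:
    """Off-diagonal count, percent error and per-class accuracy."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    mis = int(total - diag.sum())
    row_totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class = np.where(row_totals > 0, diag / row_totals, np.nan)
    return {
        "misclassified": mis,
        "error_pct": 100.0 * mis / total,
        "per_class_accuracy": dict(zip(cm.class_order, per_class.tolist())),
    }


@dataclass(frozen=True)
class SplitEvaluation:
    """Outcome of repeated stratified calibration/prediction splits."""

    mean_error_pct: float
    per_split_error_pct: np.ndarray
    matrices: tuple

    @property
    def aggregate(self) -> ConfusionMatrix:
        """Sum of the per-split confusion matrices."""
        total = sum(cm.counts for cm in self.matrices)
        return ConfusionMatrix(class_order=self.matrices[0].class_order, counts=total)


def repeated_split_evaluate(
    X: np.ndarray,
    y: Sequence,
    config: HyperparamConfig,
    n_components: int,
    n_repeats: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    class_order: Optional[Sequence[str]] = None,
    max_retries: int = 20,
) -> SplitEvaluation:
    """Assess a tuned configuration by repeated stratified holdout.

    Each repeat draws a stratified calibration/prediction split
    (calibration size = round-half-up of train_frac * n), fits PCA on
    the calibration part only, trains the SVM on its leading
    ``n_components`` scores, and scores the prediction part. A split
    leaving any class out of calibration is redrawn up to
    ``max_retries`` times before erroring.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    if class_order is None:
        class_order = [c for c in CLASS_ORDER if c in set(classes)] or sorted(classes)
    n_cal = calibration_size(n, train_frac)
    rng = np.random.default_rng(seed)

    errors = []
    matrices = []
    for _ in range(n_repeats):
        for attempt in range(max_retries + 1):
            cal, pred_idx = stratified_split(y, n_cal, rng)
            Xc, Xp, yc, yp = X[cal], X[pred_idx], y[cal], y[pred_idx]
            if set(np.unique(yc)) == set(classes):
                break
        else:
            raise CSAError("could not draw a split covering every class in calibration")
        pca = fit_pca(Xc)
        k = min(n_components, pca.n_components)
        clf = train_svm(pca.transform(Xc, k), yc, config)
        pred = clf.predict(pca.transform(Xp, k))
        errors.append(100.0 * float((pred != yp).mean()))
        counts = _sk_confusion(yp, pred, labels=list(class_order))
        matrices.append(ConfusionMatrix(class_order=tuple(class_order), counts=counts))
    return SplitEvaluation(
        mean_error_pct=float(np.mean(errors)),
        per_split_error_pct=np.array(errors),
        matrices=tuple(matrices),
    )
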