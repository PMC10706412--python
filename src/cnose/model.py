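"""Model/Results interface over the chemometric pipeline.

`AdulterationModel` holds a fingerprint table with class labels;
`fit()` performs the whole tuning-and-validation protocol — centred
PCA, principal-component selection at a cumulative-variance threshold,
random-search SVM tuning against a stratified 10-fold CV error on a
calibration split, and repeated stratified 70/30 holdout evaluation —
and returns an `AdulterationResults` carrying the tuned configuration,
the search trace, per-split errors, confusion matrices, a final
all-data classifier, a text `summary()` and plotting helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .chemometrics import (
    ConfusionMatrix,
    HyperparamConfig,
    PCAModel,
    SearchTrace,
    SplitEvaluation,
)
from .exceptions import CSAError, DataFormatError
from .features import FEATURE_COLUMNS
from .scheme import CLASS_ORDER

__all__ = ["AdulterationModel", "AdulterationResults"]

SCHEMA_VERSION = 1


class AdulterationModel:
    """Adulteration classifier built from an n x 18 fingerprint table.

    Parameters
    ----------
    X : array-like, shape (n, 18)
        Colour-change fingerprints (mean |post - pre| per spot/channel).
    y : sequence of str
        Class labels (the 13-class scheme, or any label set).
    variance_threshold : float
        Cumulative explained-variance fraction used to pick the number
        of principal components fed to the classifier (default 0.95).
    """

    def __init__(self, X, y, variance_threshold: float = 0.95):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes")
        self.X = X
        self.y = y
        self.variance_threshold = variance_threshold
        known = set(np.unique(y))
        self.class_order = [c for c in CLASS_ORDER if c in known] or sorted(known)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_columns: Sequence[str] = tuple(FEATURE_COLUMNS),
        label_column: str = "label",
        **kwargs,
    ) -> "AdulterationModel":
        missing = [c for c in (*feature_columns, label_column) if c not in df.columns]
        if missing:
            raise DataFormatError(f"feature table is missing columns: {missing}")
        return cls(df[list(feature_columns)].to_numpy(float), df[label_column].to_numpy(), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AdulterationModel":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def fit(
        self,
        n_iter: int = 100,
        folds: int = 10,
        n_repeats: int = 10,
        train_frac: float = 0.7,
        n_components: Optional[int] = None,
        seed: int = 0,
    ) -> "AdulterationResults":
        """Tune and validate the classifier.

        A stratified calibration split (fraction ``train_frac``) is drawn
        for tuning: PCA is fitted on it, the component count is chosen at
        the variance threshold (unless ``n_components`` overrides it),
        and ``n_iter`` random-search evaluations of the stratified
        ``folds``-fold CV error pick the configuration. The tuned
        configuration is then assessed by ``n_repeats`` fresh stratified
        splits. All randomness derives from ``seed``.
        """
        rng = np.random.default_rng(seed)
        search_seed = int(rng.integers(2**31 - 1))
        eval_seed = int(rng.integers(2**31 - 1))

        n_cal = chem.calibration_size(len(self.y), train_frac)
        cal_idx, _ = chem.stratified_split(self.y, n_cal, rng)
        Xc, yc = self.X[cal_idx], self.y[cal_idx]
        pca_cal = chem.fit_pca(Xc)
        if n_components is None:
            k = chem.select_n_components(pca_cal, self.variance_threshold)
        else:
            k = int(n_components)
            if not 1 <= k <= pca_cal.n_components:
                raise ValueError(f"n_components must lie in [1, {pca_cal.n_components}]")
        trace, best = chem.random_search(
            pca_cal.transform(Xc, k), yc, n_iter=n_iter, folds=folds, seed=search_seed
        )
        evaluation = chem.repeated_split_evaluate(
            self.X, self.y, best, n_components=k,
            n_repeats=n_repeats, train_frac=train_frac, seed=eval_seed,
            class_order=self.class_order,
        )

        # Final artefacts on the full dataset, for prediction and export.
        pca_full = chem.fit_pca(self.X)
        k_full = min(k, pca_full.n_components)
        classifier = chem.train_svm(pca_full.transform(self.X, k_full), self.y, best)

        return AdulterationResults(
            model=self,
            config=best,
            n_components=k,
            pca=pca_full,
            search_trace=trace,
            cv_objective=trace.best[1],
            evaluation=evaluation,
            seed=seed,
            _classifier=classifier,
        )


@dataclass
class AdulterationResults:
    """Fitted results: tuned hyperparameters, search trace, PCA model,
    repeated-split evaluation and a final all-data classifier."""

    model: AdulterationModel
    config: HyperparamConfig
    n_components: int
    pca: PCAModel
    search_trace: SearchTrace
    cv_objective: float
    evaluation: SplitEvaluation
    seed: int
    _classifier: object = field(default=None, repr=False)

    @property
    def mean_error_pct(self) -> float:
        return self.evaluation.mean_error_pct

    @property
    def aggregate_confusion(self) -> ConfusionMatrix:
        return self.evaluation.aggregate

    def predict(self, X) -> np.ndarray:
        """Classify new fingerprints with the final all-data classifier."""
        X = np.asarray(X, dtype=float)
        k = min(self.n_components, self.pca.n_components)
        return self._classifier.predict(self.pca.transform(X, k))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        stats = chem.confusion_stats(self.aggregate_confusion)
        cum = float(np.cumsum(self.pca.explained_ratio)[self.n_components - 1])
        lines = [
            "Adulteration classification results",
            "=" * 55,
            f"Samples:                 {len(self.model.y)}",
            f"Classes:                 {len(self.model.class_order)}",
            f"Principal components:    {self.n_components} "
            f"({100 * cum:.1f}% variance explained)",
            f"Search evaluations:      {len(self.search_trace.evaluations)}",
            f"Best CV objective:       {100 * self.cv_objective:.2f}% error",
            "-" * 55,
            "Tuned hyperparameters:",
            f"  kernel:                {cfg.kernel}"
            + (f" (order {cfg.poly_order})" if cfg.kernel == "polynomial" else ""),
            f"  box constraint:        {cfg.box_constraint:.5g}",
            f"  kernel scale:          "
            + (f"{cfg.kernel_scale:.5g}" if cfg.kernel_scale is not None else "-"),
            f"  standardize:           {cfg.standardize}",
            "-" * 55,
            f"Repeated-split error:    {self.mean_error_pct:.2f}% "
            f"(mean of {len(self.evaluation.matrices)} stratified splits)",
            f"Pooled misclassified:    {stats['misclassified']} / "
            f"{self.aggregate_confusion.total}",
            f"Seed:                    {self.seed}",
        ]
        return "\n".join(lines)

    def confusion_frame(self) -> pd.DataFrame:
        cm = self.aggregate_confusion
        return pd.DataFrame(cm.counts, index=cm.class_order, columns=cm.class_order)

    # -- plotting -----------------------------------------------------------

    def plot_search_trace(self, ax=None):
        """Minimum-observed CV error versus function evaluation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mo = 100 * self.search_trace.min_observed
        ax.step(np.arange(1, len(mo) + 1), mo, where="post")
        ax.set_xlabel("Function evaluation")
        ax.set_ylabel("Minimum observed CV error (%)")
        ax.set_title("Random-search tuning trace")
        return ax

    def plot_scores(self, components=(0, 1), ax=None):
        """Scatter of samples in principal-component score space."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scores = self.pca.transform(self.model.X)
        i, j = components
        for cls in self.model.class_order:
            sel = self.model.y == cls
            ax.scatter(scores[sel, i], scores[sel, j], label=cls, s=18)
        ax.set_xlabel(f"PC{i + 1}")
        ax.set_ylabel(f"PC{j + 1}")
        ax.legend(fontsize=7, ncol=2)
        return ax

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        svc = self._classifier.named_steps["svc"]
        scaler = self._classifier.named_steps.get("scale")
        return {
            "schema_version": SCHEMA_VERSION,
            "class_order": list(self.model.class_order),
            "config": self.config.to_dict(),
            "n_components": self.n_components,
            "seed": self.seed,
            "pca": {
                "means": self.pca.means.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "explained_ratio": self.pca.explained_ratio.tolist(),
            },
            "svm": {
                "support_vectors": svc.support_vectors_.tolist(),
                "dual_coef": svc.dual_coef_.tolist(),
                "intercept": svc.intercept_.tolist(),
                "classes": [str(c) for c in svc.classes_],
                "scaler_mean": scaler.mean_.tolist() if scaler is not None else None,
                "scaler_scale": scaler.scale_.tolist() if scaler is not None else None,
            },
            "search": {
                "objectives": self.search_trace.objectives.tolist(),
                "min_observed": self.search_trace.min_observed.tolist(),
                "best_objective": self.cv_objective,
            },
            "evaluation": {
                "mean_error_pct": self.mean_error_pct,
                "per_split_error_pct": self.evaluation.per_split_error_pct.tolist(),
                "aggregate_confusion": self.aggregate_confusion.counts.tolist(),
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def load_artifact(path) -> dict:
        """Load a serialised model artefact (dict form; the tuned config is
        under ``config`` and can be refit on any feature table)."""
        with open(path) as fh:
            d = json.load(fh)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise DataFormatError(
                f"unsupported model schema version {d.get('schema_version')}"
            )
        return d
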