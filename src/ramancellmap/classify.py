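"""Feature reduction, train/test protocol and the ten-classifier battery.

Purified spectra are reduced either to their first principal-component
scores (15 by default) or to a 2-D t-SNE embedding, split 3:1 into training
and testing partitions, and used to train ten classifier families:
RBF and linear support vector machines, random forest, linear and quadratic
discriminant analysis, partial least squares (PLS-DA), k-nearest
neighbors, a single-hidden-layer neural network ("nnet"), a multilayer
perceptron and Gaussian naive Bayes.  Each family is tuned by repeated
stratified k-fold cross-validation (10-fold x 5 repeats) over a small
hyperparameter grid, then evaluated on the held-out test partition with the
cancer-like class as positive.

Note on the reduction protocol: dimensionality reduction is fitted on the
full labeled dataset *before* splitting, replicating the published
workflow; the information leakage this implies is deliberate and
documented.  A fit-on-training-only mode is available for PCA (t-SNE has no
out-of-sample transform in the backend used here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import LabeledSpectraSet
from .denoise import fit_pca
from .errors import InvalidArgumentError, StratificationError
from .synthdata import CLASS_A

__all__ = [
    "ReductionSpec",
    "SplitSpec",
    "CVConfig",
    "ClassifierMetrics",
    "EvalReport",
    "FAMILIES",
    "reduce_features",
    "split_train_test",
    "train_models",
    "evaluate",
    "PLSDAClassifier",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReductionSpec:
    """Feature reduction: ``pca`` (first n score columns) or ``tsne`` (2-D)."""

    method: str = "pca"
    n_components: int = 15
    perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pca", "tsne"):
            raise InvalidArgumentError("method must be 'pca' or 'tsne'")
        if self.n_components < 1:
            raise InvalidArgumentError("n_components must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split; 3:1 by default, round-half-up train size."""

    train_fraction: float = 0.75
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise InvalidArgumentError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold CV used for model tuning (10-fold x 5)."""

    folds: int = 10
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise InvalidArgumentError("folds must be >= 2")
        if self.repeats < 1:
            raise InvalidArgumentError("repeats must be >= 1")


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------


def reduce_features(
    spectra: LabeledSpectraSet,
    spec: ReductionSpec = ReductionSpec(),
    fit_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce spectra to classifier features; returns (features, labels).

    The PCA path reuses the denoising decomposition and returns the first
    ``n_components`` score columns; t-SNE returns a 2-column embedding,
    deterministic given ``spec.seed``.  ``fit_mask`` restricts the rows used
    to *fit* the reduction (PCA only): features for all rows are still
    returned, projected on the restricted fit.
    """
    X = spectra.matrix
    n = X.shape[0]
    if n <= spec.n_components:
        raise InvalidArgumentError("need more spectra than components")
    if spec.method == "pca":
        if fit_mask is not None:
            model = fit_pca(X[fit_mask])
            if spec.n_components > model.n_pc:
                raise InvalidArgumentError("n_components exceeds available PCs")
            feats = (X - model.mean_spectrum) @ model.loadings[: spec.n_components].T
        else:
            model = fit_pca(X)
            if spec.n_components > model.n_pc:
                raise InvalidArgumentError("n_components exceeds available PCs")
            feats = model.scores[:, : spec.n_components]
        return feats, spectra.labels.copy()
    # t-SNE
    if fit_mask is not None and not np.all(fit_mask):
        raise InvalidArgumentError(
            "t-SNE has no out-of-sample transform; fit_mask is not supported"
        )
    if spec.perplexity >= (n - 1) / 3:
        raise InvalidArgumentError(
            f"perplexity {spec.perplexity} infeasible for n={n} (must be < (n-1)/3)"
        )
    emb = TSNE(
        n_components=2,
        perplexity=spec.perplexity,
        random_state=spec.seed,
        init="pca",
    ).fit_transform(X)
    return np.asarray(emb, dtype=float), spectra.labels.copy()


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(
    features: np.ndarray,
    labels: np.ndarray,
    spec: SplitSpec = SplitSpec(),
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Random disjoint, exhaustive train/test split.

    The train size is ``round-half-up(n * train_fraction)`` — the rule that
    maps 2530 spectra at 3:1 to exactly 1898/632.  With ``stratified=True``
    class proportions are preserved to within one observation per class.
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 4 or y.shape[0] != n:
        raise InvalidArgumentError("need n >= 4 features with matching labels")
    n_train = _round_half_up(n * spec.train_fraction)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
    else:
        classes, counts = np.unique(y, return_counts=True)
        takes = {c: _round_half_up(k * spec.train_fraction) for c, k in zip(classes, counts)}
        # reconcile the per-class roundings with the global train size
        order = list(classes[np.argsort(-counts)])
        i = 0
        while sum(takes.values()) > n_train:
            takes[order[i % len(order)]] -= 1
            i += 1
        while sum(takes.values()) < n_train:
            c = order[i % len(order)]
            if takes[c] < counts[list(classes).index(c)]:
                takes[c] += 1
            i += 1
        if any(t < 1 for t in takes.values()):
            raise StratificationError("a class would be absent from the training set")
        tr_parts, te_parts = [], []
        for c in classes:
            idx = rng.permutation(np.nonzero(y == c)[0])
            tr_parts.append(idx[: takes[c]])
            te_parts.append(idx[takes[c]:])
        tr = rng.permutation(np.concatenate(tr_parts))
        te = rng.permutation(np.concatenate(te_parts))
    return (X[tr], y[tr]), (X[te], y[te])


# ---------------------------------------------------------------------------
# classifier families
# ---------------------------------------------------------------------------


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis: PLS regression on class indicators.

    Class membership is one-hot encoded, a partial-least-squares regression
    is fitted, and predictions take the class with the largest predicted
    indicator.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, yi = np.unique(y, return_inverse=True)
        Y = np.eye(len(self.classes_))[yi]
        ncomp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self._pls = PLSRegression(n_components=max(1, ncomp))
        self._pls.fit(X, Y)
        return self

    def predict(self, X):
        scores = self._pls.predict(np.asarray(X, dtype=float))
        return self.classes_[np.argmax(scores, axis=1)]


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _family_grid(family: str, seed: int) -> tuple[BaseEstimator, dict]:
    """Estimator + small hyperparameter grid for one classifier family."""
    if family == "svm-rbf":
        return _scaled(SVC(kernel="rbf", random_state=seed)), {
            "model__C": [1.0, 10.0, 100.0],
            "model__gamma": ["scale", 0.1, 0.01],
        }
    if family == "svm-linear":
        return _scaled(SVC(kernel="linear", random_state=seed)), {
            "model__C": [0.1, 1.0, 10.0],
        }
    if family == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed), {
            "max_features": ["sqrt", 0.5],
        }
    if family == "lda":
        return LinearDiscriminantAnalysis(), {}
    if family == "qda":
        return QuadraticDiscriminantAnalysis(), {"reg_param": [0.0, 1e-3]}
    if family == "pls":
        return PLSDAClassifier(), {"n_components": [2, 4, 8]}
    if family == "knn":
        return _scaled(KNeighborsClassifier()), {"model__n_neighbors": [3, 5, 7, 9]}
    if family == "nnet":
        # single hidden layer with weight decay, lbfgs for small nets
        return _scaled(
            MLPClassifier(solver="lbfgs", alpha=1e-3, max_iter=1000, random_state=seed)
        ), {"model__hidden_layer_sizes": [(3,), (5,), (8,)]}
    if family == "mlp":
        return _scaled(
            MLPClassifier(solver="lbfgs", alpha=1e-4, max_iter=1000, random_state=seed)
        ), {"model__hidden_layer_sizes": [(10, 5), (8, 4)]}
    if family == "nb":
        return GaussianNB(), {}
    raise InvalidArgumentError(f"unknown classifier family {family!r}")


#: The ten classifier families, in the conventional reporting order.
FAMILIES: tuple[str, ...] = (
    "svm-rbf", "svm-linear", "rf", "lda", "qda", "pls", "knn", "nnet", "mlp", "nb",
)


@dataclass
class FittedFamily:
    """Tuning result for one family."""

    family: str
    estimator: BaseEstimator  # refitted on the full training partition
    cv_accuracy: float
    best_params: dict


def train_models(
    features: np.ndarray,
    labels: np.ndarray,
    cv: CVConfig = CVConfig(),
    families: tuple[str, ...] | list[str] | str = "all",
) -> dict[str, FittedFamily]:
    """Tune and fit the requested classifier families.

    Each family runs a grid search over its small documented grid with
    repeated stratified k-fold CV; ``cv_accuracy`` is the best mean
    resampling accuracy, and the returned estimator is refitted on the full
    training partition.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise InvalidArgumentError("need at least two classes to train")
    if families == "all":
        families = FAMILIES
    registry: dict[str, FittedFamily] = {}
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    for family in families:
        est, grid = _family_grid(family, cv.seed)
        if grid:
            search = GridSearchCV(est, grid, cv=splitter, scoring="accuracy", n_jobs=None)
            search.fit(X, y)
            registry[family] = FittedFamily(
                family, search.best_estimator_, float(search.best_score_),
                dict(search.best_params_),
            )
        else:
            from sklearn.model_selection import cross_val_score

            acc = cross_val_score(est, X, y, cv=splitter, scoring="accuracy")
            fitted = clone(est).fit(X, y)
            registry[family] = FittedFamily(family, fitted, float(acc.mean()), {})
    return registry


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ClassifierMetrics:
    """Confusion counts and derived rates, positive = cancer-like class."""

    tp: int
    fp: int
    tn: int
    fn: int
    cv_accuracy: float = float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(1, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / max(1, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / max(1, self.tn + self.fp)


@dataclass
class EvalReport:
    """Per-family test-set performance."""

    metrics: dict[str, ClassifierMetrics] = field(default_factory=dict)
    positive_label: str = CLASS_A

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family, m in self.metrics.items():
            rows.append({
                "family": family, "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                "cv_accuracy": m.cv_accuracy, "accuracy": m.accuracy,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
            })
        return pd.DataFrame(rows)

    def min_accuracy(self, exclude: tuple[str, ...] = ()) -> float:
        accs = [m.accuracy for f, m in self.metrics.items() if f not in exclude]
        return min(accs)


def confusion_counts(y_true, y_pred, positive: str) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    return tp, fp, tn, fn


def evaluate(
    registry: dict[str, FittedFamily],
    features: np.ndarray,
    labels: np.ndarray,
    positive: str = CLASS_A,
) -> EvalReport:
    """Test-partition confusion matrices and accuracy/sensitivity/specificity."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise InvalidArgumentError("test partition is empty")
    report = EvalReport(positive_label=positive)
    for family, fitted in registry.items():
        pred = fitted.estimator.predict(X)
        tp, fp, tn, fn = confusion_counts(y, pred, positive)
        report.metrics[family] = ClassifierMetrics(tp, fp, tn, fn, fitted.cv_accuracy)
    return report
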