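"""Metrics, confusion matrices, baselines, and the split-sweep benchmark.

Metrics are macro-averaged (unweighted over classes), matching the fairness
emphasis of balanced training: a minority manufacturer's recall counts as
much as a majority one's.  F1 is the harmonic mean of macro precision and
macro recall.

The classical chemometric baselines run at their conventional settings:
PLS-DA with 30 latent components (one-hot indicator regression, nearest
indicator decision), linear SVM (C=1), RBF SVM (gamma=1e-4, C=1),
1-nearest-neighbour, and a single-layer sigmoid network (BP-ANN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import SpectralDataset
from .dataops import stratified_split

__all__ = [
    "EvalReport",
    "BenchmarkGrid",
    "confusion_matrix",
    "classification_metrics",
    "baseline_harness",
    "BASELINE_NAMES",
    "run_benchmark",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix and macro metrics of one evaluation run."""

    confusion: np.ndarray     # (k, k) counts, rows = true, cols = predicted
    precision: float          # macro
    recall: float             # macro
    f1: float                 # harmonic mean of macro precision and recall
    accuracy: float
    train_fraction: float | None = None
    seed: int | None = None
    repetition: int | None = None
    method: str | None = None


def confusion_matrix(true: np.ndarray, predicted: np.ndarray, k: int) -> np.ndarray:
    """Count matrix with entry (i, j) = samples of true class i+1 predicted j+1."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true.shape != predicted.shape:
        raise ValueError("label arrays must have equal length")
    for name, arr in (("true", true), ("predicted", predicted)):
        if arr.size and (arr.min() < 1 or arr.max() > k):
            raise ValueError(f"{name} labels must lie in 1..{k}")
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (true - 1, predicted - 1), 1)
    return cm


def classification_metrics(cm: np.ndarray) -> tuple[float, float, float, float]:
    """(macro precision, macro recall, F1, accuracy) from a confusion matrix.

    Per-class precision/recall with a zero denominator are counted as 0; F1
    is the harmonic mean of the two macro averages.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    precision = float(np.mean(np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)))
    recall = float(np.mean(np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)))
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    accuracy = float(diag.sum() / total)
    return precision, recall, f1, accuracy


def evaluate_predictions(true: np.ndarray, predicted: np.ndarray, k: int,
                         **meta) -> EvalReport:
    cm = confusion_matrix(true, predicted, k)
    p, r, f1, acc = classification_metrics(cm)
    return EvalReport(confusion=cm, precision=p, recall=r, f1=f1, accuracy=acc, **meta)


# ---------------------------------------------------------------------------
# classical baselines


class _PLSDA:
    """PLS regression on one-hot targets; decision = nearest class indicator."""

    def __init__(self, n_components: int = 30):
        self.n_components = n_components
        self._pls: PLSRegression | None = None
        self._classes: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PLSDA":
        self._classes = np.unique(y)
        Y = (np.asarray(y)[:, None] == self._classes[None, :]).astype(float)
        n_comp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self._pls = PLSRegression(n_components=n_comp, scale=False)
        self._pls.fit(X, Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self._pls.predict(X)
        # nearest one-hot indicator in Euclidean distance == argmax score
        return self._classes[np.argmax(scores, axis=1)]


class _BPANN:
    """Single affine layer with sigmoid outputs, cross-entropy trained."""

    def __init__(self, epochs: int = 200, lr: float = 1e-3, batch_size: int = 60,
                 rng_seed: int = 0):
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.rng_seed = rng_seed
        self._W = None
        self._b = None
        self._classes = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BPANN":
        from .nn import sigmoid  # lightweight reuse

        rng = np.random.default_rng(self.rng_seed)
        X = np.asarray(X, dtype=float)
        self._classes = np.unique(y)
        Y = (np.asarray(y)[:, None] == self._classes[None, :]).astype(float)
        n, L = X.shape
        k = len(self._classes)
        self._W = rng.normal(0, np.sqrt(2.0 / L), size=(L, k))
        self._b = np.zeros(k)
        cache_W, cache_b = np.zeros_like(self._W), np.zeros_like(self._b)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                rows = order[s:s + self.batch_size]
                p = sigmoid(X[rows] @ self._W + self._b)
                g = (p - Y[rows]) / len(rows)
                dW, db = X[rows].T @ g, g.sum(axis=0)
                cache_W = 0.9 * cache_W + 0.1 * dW * dW
                cache_b = 0.9 * cache_b + 0.1 * db * db
                self._W -= self.lr * dW / (np.sqrt(cache_W) + 1e-7)
                self._b -= self.lr * db / (np.sqrt(cache_b) + 1e-7)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._classes[np.argmax(np.asarray(X, dtype=float) @ self._W + self._b, axis=1)]


BASELINE_NAMES = ("pls-da", "linear-svm", "rbf-svm", "knn", "bp-ann")


def baseline_harness(name: str, **hyperparameters):
    """A trainable classical method (fit/predict) at its standard settings.

    Known names: ``pls-da`` (30 components), ``linear-svm`` (C=1),
    ``rbf-svm`` (gamma=1e-4, C=1), ``knn`` (k=1), ``bp-ann`` (single
    sigmoid layer).  Keyword arguments override the defaults.
    """
    name = name.lower()
    if name == "pls-da":
        return _PLSDA(n_components=hyperparameters.get("n_components", 30))
    if name == "linear-svm":
        return SVC(kernel="linear", C=hyperparameters.get("C", 1.0))
    if name == "rbf-svm":
        return SVC(kernel="rbf", C=hyperparameters.get("C", 1.0),
                   gamma=hyperparameters.get("gamma", 1e-4))
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=hyperparameters.get("k", 1))
    if name == "bp-ann":
        return _BPANN(**hyperparameters)
    raise ValueError(f"unknown baseline {name!r}; known: {BASELINE_NAMES}")


# ---------------------------------------------------------------------------
# split-sweep benchmark


DEFAULT_RATIOS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)


@dataclass
class BenchmarkGrid:
    """Split-sweep protocol and its results.

    Per (method, ratio) the headline is the *best* accuracy over the
    repetitions (the historical protocol of the benchmark), but every
    repetition's report is retained so mean +- sd can always be derived.
    """

    ratios: tuple[float, ...] = DEFAULT_RATIOS
    repetitions: int = 10
    reports: list[EvalReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def best_accuracy(self, method: str, ratio: float) -> float:
        accs = [r.accuracy for r in self.reports
                if r.method == method and r.train_fraction == ratio]
        if not accs:
            raise KeyError(f"no reports for {method} at {ratio}")
        return max(accs)

    def accuracy_stats(self, method: str, ratio: float) -> tuple[float, float]:
        accs = [r.accuracy for r in self.reports
                if r.method == method and r.train_fraction == ratio]
        return float(np.mean(accs)), float(np.std(accs))


def run_benchmark(dataset: SpectralDataset, methods: dict[str, callable],
                  grid: BenchmarkGrid | None = None, rng_seed: int = 0,
                  on_error: str = "record") -> BenchmarkGrid:
    """Train and evaluate each method over fresh splits of every ratio.

    `methods` maps a name to a zero-argument factory returning a fit/predict
    object.  Each (ratio, repetition) uses a fresh stratified split; all
    repetitions are retained.  A method failure is recorded as a skipped
    report unless ``on_error='raise'``.
    """
    grid = grid or BenchmarkGrid()
    k = int(dataset.class_ids.max())
    for ratio in grid.ratios:
        for rep in range(grid.repetitions):
            seed = int(np.random.default_rng(
                np.random.SeedSequence([rng_seed, int(round(ratio * 100)), rep])
            ).integers(2**31))
            split = stratified_split(dataset, ratio, rng_seed=seed)
            tr, te = split.all_train(), split.all_test()
            for name, factory in methods.items():
                try:
                    clf = factory()
                    clf.fit(dataset.X[tr], dataset.class_ids[tr])
                    pred = clf.predict(dataset.X[te])
                    grid.reports.append(evaluate_predictions(
                        dataset.class_ids[te], np.asarray(pred, dtype=int), k,
                        train_fraction=ratio, seed=seed, repetition=rep, method=name))
                except Exception:
                    if on_error == "raise":
                        raise
    return grid
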