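"""Balanced repeated-split random-forest training and evaluation protocol.

One protocol run repeats, over ``n_iterations`` recorded seeds: draw a
class-balanced 70/30-style split (equal per-class counts in training,
sampled without replacement from independent per-class streams; everything
else is test), fit a random forest of fully grown trees (bootstrap
resampling, sqrt(p) features per split, majority/probability voting), and
score it on the held-out rows with the secreted class as positive. The
best model is the highest-test-accuracy run; Gini feature importances are
averaged over the top-k runs (default 7) and features below a 2% mean
importance are pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitSpec",
    "Metrics",
    "TrainedRun",
    "ProtocolResult",
    "InsufficientClassError",
    "DegenerateTrainingError",
    "SchemaError",
    "DEFAULT_RF_PARAMS",
    "f1_from_precision_recall",
    "balanced_split",
    "train_forest",
    "evaluate",
    "run_protocol",
    "prune_by_importance",
    "compare_algorithms",
]

POSITIVE_CLASS = "secreted"

DEFAULT_RF_PARAMS: dict = {
    "n_estimators": 500,
    "max_depth": None,        # fully grown trees
    "max_features": "sqrt",   # random feature subsets per split
    "bootstrap": True,
}


class InsufficientClassError(ValueError):
    """A class has fewer rows than the balanced per-class training size."""


class DegenerateTrainingError(ValueError):
    """Training rows contain a single class."""


class SchemaError(ValueError):
    """Evaluation features do not match the training features."""


@dataclass(frozen=True)
class SplitSpec:
    """Split protocol: training fraction, iteration count, balancing."""

    train_fraction: float = 0.70
    n_iterations: int = 150
    balance: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: dict[str, int]          # tp/fp/tn/fn, positive = secreted
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)


@dataclass
class TrainedRun:
    seed: int
    forest: RandomForestClassifier
    feature_names: list[str]
    metrics: Metrics
    importances: pd.Series  # Gini importances, sum to 1


@dataclass
class ProtocolResult:
    runs: list[TrainedRun]
    best: TrainedRun
    top_k: list[TrainedRun]
    mean_importances: pd.Series
    accuracies: np.ndarray = field(default_factory=lambda: np.zeros(0))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _split_xy(t: pd.DataFrame, label_col: str = "class"):
    X = t.drop(columns=[label_col])
    y = t[label_col]
    return X, y


def balanced_split(
    t: pd.DataFrame,
    spec: SplitSpec,
    seed: int,
    label_col: str = "class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-balanced train/test split.

    Training size is ``round(train_fraction * n_rows)`` divided equally
    among the classes (floor); each class is sampled without replacement
    from its own seeded stream; all remaining rows form the test set.
    """
    classes = sorted(t[label_col].unique())
    if len(classes) < 2:
        raise InsufficientClassError("need at least two classes to split")
    n_train = round(spec.train_fraction * len(t))
    n_per_class = n_train // len(classes)
    streams = np.random.SeedSequence(seed).spawn(len(classes))
    train_idx: list = []
    for cls, stream in zip(classes, streams):
        members = t.index[t[label_col] == cls]
        if len(members) < n_per_class:
            raise InsufficientClassError(
                f"class {cls!r} has {len(members)} rows < per-class training "
                f"size {n_per_class}"
            )
        rng = np.random.default_rng(stream)
        picked = rng.choice(len(members), size=n_per_class, replace=False)
        train_idx.extend(members[np.sort(picked)])
    train = t.loc[train_idx]
    test = t.loc[t.index.difference(train_idx, sort=False)]
    return train, test


def train_forest(
    train: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    label_col: str = "class",
) -> RandomForestClassifier:
    """Fit the random forest on a training table (features + label column)."""
    X, y = _split_xy(train, label_col)
    if y.nunique() < 2:
        raise DegenerateTrainingError("training data contains a single class")
    params = {**DEFAULT_RF_PARAMS, **(hyperparams or {})}
    forest = RandomForestClassifier(random_state=seed, **params)
    forest.fit(X, y)
    return forest


def evaluate(
    forest,
    test: pd.DataFrame,
    label_col: str = "class",
    positive: str = POSITIVE_CLASS,
) -> Metrics:
    """Test-set metrics with ``positive`` (secreted) as the positive class."""
    if test.empty:
        raise ValueError("test set is empty")
    X, y = _split_xy(test, label_col)
    trained = list(getattr(forest, "feature_names_in_", X.columns))
    if set(X.columns) != set(trained):
        raise SchemaError(
            f"test features {sorted(X.columns)} != training features {sorted(trained)}"
        )
    X = X[trained]

    y_pred = forest.predict(X)
    y_true = y.to_numpy()
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))
    accuracy = (tp + tn) / len(y_true)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0

    classes = list(forest.classes_)
    score = None
    if positive in classes and len(np.unique(y_true)) > 1:
        try:
            score = forest.predict_proba(X)[:, classes.index(positive)]
        except AttributeError:
            if hasattr(forest, "decision_function"):
                df = forest.decision_function(X)  # oriented toward classes_[1]
                score = df if classes.index(positive) == 1 else -df
    if score is not None:
        fpr, tpr, _ = roc_curve(y_true == positive, score)
        area = float(auc(fpr, tpr))  # trapezoidal
    else:
        fpr = tpr = np.array([0.0, 1.0])
        area = float("nan")

    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        auc=area,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc=(fpr, tpr),
    )


def _iteration_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def run_protocol(
    t: pd.DataFrame,
    spec: SplitSpec | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
    top_k: int = 7,
    label_col: str = "class",
    model_factory=None,
) -> ProtocolResult:
    """Run the full repeated-split protocol and summarize it.

    Per-iteration seeds are drawn once from ``seed`` and recorded on each
    :class:`TrainedRun`. ``model_factory(seed) -> estimator`` overrides the
    forest (used for the algorithm comparison); Gini importances are only
    collected from estimators that expose them.
    """
    spec = spec or SplitSpec()
    seeds = _iteration_seeds(seed, spec.n_iterations)
    runs: list[TrainedRun] = []
    for it_seed in seeds:
        it_seed = int(it_seed)
        train, test = balanced_split(t, spec, it_seed, label_col)
        if model_factory is None:
            model = train_forest(train, hyperparams, seed=it_seed, label_col=label_col)
        else:
            model = model_factory(it_seed)
            X, y = _split_xy(train, label_col)
            model.fit(X, y)
        metrics = evaluate(model, test, label_col)
        feature_names = [c for c in t.columns if c != label_col]
        if hasattr(model, "feature_importances_"):
            imp = pd.Series(model.feature_importances_, index=feature_names)
        else:
            imp = pd.Series(np.nan, index=feature_names)
        runs.append(TrainedRun(it_seed, model, feature_names, metrics, imp))

    accs = np.array([r.metrics.accuracy for r in runs])
    order = np.argsort(-accs, kind="stable")
    best = runs[order[0]]
    top = [runs[i] for i in order[: min(top_k, len(runs))]]
    if not np.isnan(top[0].importances.iloc[0]):
        mean_imp = pd.concat([r.importances for r in top], axis=1).mean(axis=1)
    else:
        mean_imp = top[0].importances
    return ProtocolResult(
        runs=runs, best=best, top_k=top, mean_importances=mean_imp, accuracies=accs
    )


def prune_by_importance(
    result: ProtocolResult | pd.Series | dict[str, float],
    floor: float = 0.02,
) -> list[str]:
    """Features whose mean top-k Gini importance is >= ``floor`` (strict
    less-than drops), ordered by descending importance. At least the two
    most important features are always retained."""
    if isinstance(result, ProtocolResult):
        imp = result.mean_importances
    else:
        imp = pd.Series(result)
    imp = imp.sort_values(ascending=False, kind="stable")
    kept = [name for name, v in imp.items() if not v < floor]
    if len(kept) < 2:
        kept = list(imp.index[:2])
    return kept


def compare_algorithms(
    t: pd.DataFrame,
    spec: SplitSpec | None = None,
    seed: int = 0,
    label_col: str = "class",
    algorithms: list[str] | None = None,
) -> dict[str, dict]:
    """Accuracy distributions of five off-the-shelf learners under the same
    repeated-split protocol. All but the forest get feature
    standardization. Returns per-algorithm accuracy samples and a Gaussian
    kernel-density summary."""
    from scipy.stats import gaussian_kde

    spec = spec or SplitSpec()
    factories = {
        "logistic_regression": lambda s: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=s)
        ),
        "knn": lambda s: make_pipeline(StandardScaler(), KNeighborsClassifier()),
        "svm": lambda s: make_pipeline(
            StandardScaler(), SVC(probability=False, random_state=s)
        ),
        "neural_network": lambda s: make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=800, random_state=s),
        ),
        "random_forest": None,  # plain protocol forest, unscaled
    }
    names = algorithms or list(factories)
    out: dict[str, dict] = {}
    for name in names:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny tables
            res = run_protocol(
                t, spec, seed=seed, label_col=label_col, model_factory=factories[name]
            )
        accs = res.accuracies
        kde = None
        if len(accs) > 1 and np.ptp(accs) > 0:
            grid = np.linspace(max(0.0, accs.min() - 0.05), min(1.0, accs.max() + 0.05), 200)
            kde = (grid, gaussian_kde(accs)(grid))
        out[name] = {"accuracies": accs, "mean": float(accs.mean()), "kde": kde}
    return out
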