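"""Six-algorithm x six-descriptor benchmarking grid with ten-fold CV.

For each regulator module, every (algorithm, descriptor set) pair is trained
and scored with the six confusion-matrix metrics (ACC, AUC, PPV, Recall, F1,
MCC).  Feature cleaning, standardization of the real-valued descriptor block,
and SMOTE balancing are all fitted on training rows only — inside each CV
fold for cross-validation — so no information leaks from evaluation rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from epiqsar.datasets import RegulatorModule, SplitDataset, smote_balance, split_train_test
from epiqsar.featurization import DescriptorSet, FeatureCleaner, FeatureMatrix


class Algorithm(str, Enum):
    """The six benchmarked learning algorithms."""

    ANN = "ANN"  # multilayer perceptron
    KNN = "KNN"
    GNB = "GNB"
    RF = "RF"
    SVC = "SVC"
    XGB = "XGB"


#: Documented default hyperparameters; every key is overridable per config.
DEFAULT_HYPERPARAMETERS: dict[Algorithm, dict] = {
    Algorithm.ANN: {"hidden_layer_sizes": (100,), "max_iter": 500},
    Algorithm.KNN: {"n_neighbors": 5},
    Algorithm.GNB: {},
    Algorithm.RF: {"n_estimators": 500},
    Algorithm.SVC: {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    Algorithm.XGB: {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
}


@dataclass(frozen=True)
class ModelConfig:
    module: RegulatorModule
    algorithm: Algorithm
    descriptor_set: DescriptorSet
    hyperparameters: tuple = ()  # sorted (key, value) pairs; hashable
    seed: int = 0

    def hyperparameter_dict(self) -> dict:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        merged.update(dict(self.hyperparameters))
        return merged

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.module.value, self.algorithm.value, self.descriptor_set.value)


def enumerate_grid(
    modules=None, algorithms=None, descriptor_sets=None, seed: int = 0
) -> list[ModelConfig]:
    """Cartesian product of modules x algorithms x descriptor sets.

    Deterministic (module, algorithm, descriptor set) enumeration order.
    The default full grid is 5 x 6 x 6 = 180 configurations.
    """
    modules = list(modules) if modules is not None else list(RegulatorModule)
    algorithms = list(algorithms) if algorithms is not None else list(Algorithm)
    descriptor_sets = (
        list(descriptor_sets) if descriptor_sets is not None else list(DescriptorSet)
    )
    for name, values in (
        ("modules", modules),
        ("algorithms", algorithms),
        ("descriptor_sets", descriptor_sets),
    ):
        if not values:
            raise ValueError(f"{name} must be non-empty")
    return [
        ModelConfig(module=m, algorithm=a, descriptor_set=d, seed=seed)
        for m, a, d in itertools.product(modules, algorithms, descriptor_sets)
    ]


def build_estimator(algorithm: Algorithm, seed: int, hyperparameters: dict | None = None):
    params = dict(DEFAULT_HYPERPARAMETERS[algorithm])
    if hyperparameters:
        params.update(hyperparameters)
    if algorithm is Algorithm.ANN:
        return MLPClassifier(random_state=seed, **params)
    if algorithm is Algorithm.KNN:
        return KNeighborsClassifier(**params)
    if algorithm is Algorithm.GNB:
        return GaussianNB(**params)
    if algorithm is Algorithm.RF:
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm is Algorithm.SVC:
        return SVC(random_state=seed, **params)
    if algorithm is Algorithm.XGB:
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            tree_method="hist",
            **params,
        )
    raise ValueError(algorithm)


@dataclass
class TrainedClassifier:
    """A fitted per-module predictor with its preprocessing state.

    ``predict_score`` returns the estimated probability of class 1 where the
    algorithm provides one, otherwise the decision-function value (monotone
    in the class-1 probability, which is all ranking metrics need).
    """

    config: ModelConfig
    cleaner: FeatureCleaner
    scaler: StandardScaler | None
    estimator: object
    manifest: dict = field(default_factory=dict)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = self.cleaner.transform(np.asarray(X, dtype=float))
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._prepare(X)), dtype=int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        Xp = self._prepare(X)
        if hasattr(self.estimator, "predict_proba"):
            return np.asarray(self.estimator.predict_proba(Xp))[:, 1]
        return np.asarray(self.estimator.decision_function(Xp), dtype=float)


def train_classifier(
    config: ModelConfig, X_train: np.ndarray, y_train: np.ndarray
) -> TrainedClassifier:
    """Fit the full training pipeline: clean -> scale -> SMOTE -> estimator."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    cleaner = FeatureCleaner().fit(X_train)
    X = cleaner.transform(X_train)
    scaler = None
    if config.descriptor_set is DescriptorSet.DESC_1D2D:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    binary = config.descriptor_set.is_binary
    X_bal, y_bal = smote_balance(X, y_train, seed=config.seed, binary=binary)
    estimator = build_estimator(config.algorithm, config.seed, config.hyperparameter_dict())
    estimator.fit(X_bal, y_bal)
    manifest = {
        "module": config.module.value,
        "algorithm": config.algorithm.value,
        "descriptor_set": config.descriptor_set.value,
        "seed": config.seed,
        "n_train": int(len(y_train)),
        "n_after_smote": int(len(y_bal)),
        "n_features": int(X.shape[1]),
    }
    return TrainedClassifier(config, cleaner, scaler, estimator, manifest)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def compute_confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass
class MetricsReport:
    ACC: float
    AUC: float
    PPV: float
    Recall: float
    F1: float
    MCC: float
    degenerate_flags: frozenset = frozenset()

    METRIC_NAMES = ("ACC", "AUC", "PPV", "Recall", "F1", "MCC")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}


def auc_score(y_true, scores) -> float:
    """AUC as the Mann–Whitney rank statistic with midrank tie handling.

    Equivalent to the area under the ROC curve obtained by integrating the
    true-positive rate over the false-positive rate.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[y_true == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    counts: ConfusionCounts, scores_with_truth: tuple | None = None
) -> MetricsReport:
    """The six confusion-matrix metrics, with degenerate denominators flagged.

    ACC = (TP+TN)/n; PPV = TP/(TP+FP); Recall = TP/(TP+FN);
    F1 = 2 PPV Recall / (PPV+Recall);
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A metric whose denominator is zero defaults to 0 and is flagged, so grid
    tables stay numeric.  AUC requires ``scores_with_truth = (y_true, scores)``
    and is flagged missing otherwise (or when only one class is present).
    """
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    flags = set()
    n = counts.n
    acc = (TP + TN) / n if n else _flag(flags, "ACC")
    ppv = TP / (TP + FP) if (TP + FP) else _flag(flags, "PPV")
    recall = TP / (TP + FN) if (TP + FN) else _flag(flags, "Recall")
    f1 = (
        2 * ppv * recall / (ppv + recall)
        if (ppv + recall) > 0
        else _flag(flags, "F1")
    )
    mcc_den = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (
        (TP * TN - FP * FN) / np.sqrt(mcc_den) if mcc_den > 0 else _flag(flags, "MCC")
    )
    if scores_with_truth is not None:
        y_true, scores = scores_with_truth
        try:
            auc = auc_score(y_true, scores)
        except ValueError:
            auc = _flag(flags, "AUC")
    else:
        auc = _flag(flags, "AUC")
    return MetricsReport(
        ACC=float(acc),
        AUC=float(auc),
        PPV=float(ppv),
        Recall=float(recall),
        F1=float(f1),
        MCC=float(mcc),
        degenerate_flags=frozenset(flags),
    )


def _flag(flags: set, name: str) -> float:
    flags.add(name)
    return 0.0


def evaluate_on(classifier: TrainedClassifier, X, y) -> MetricsReport:
    y = np.asarray(y, dtype=int)
    y_pred = classifier.predict_label(X)
    scores = classifier.predict_score(X)
    return compute_metrics(compute_confusion(y, y_pred), (y, scores))


@dataclass
class CVReport:
    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]

    @property
    def n_folds(self) -> int:
        return len(self.fold_reports)


def cross_validate(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int | None = None,
) -> CVReport:
    """Stratified k-fold CV with the whole pipeline refitted per fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    seed = config.seed if seed is None else seed
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; use fewer folds"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports = []
    for train_idx, val_idx in splitter.split(X, y):
        clf = train_classifier(config, X[train_idx], y[train_idx])
        fold_reports.append(evaluate_on(clf, X[val_idx], y[val_idx]))
    names = MetricsReport.METRIC_NAMES
    values = {m: np.array([getattr(r, m) for r in fold_reports]) for m in names}
    return CVReport(
        fold_reports=fold_reports,
        mean={m: float(values[m].mean()) for m in names},
        std={m: float(values[m].std(ddof=0)) for m in names},
    )


@dataclass
class GridEntry:
    config: ModelConfig
    cv: CVReport | None = None
    test: MetricsReport | None = None
    error: str | None = None


@dataclass
class GridResult:
    entries: list[GridEntry]

    def for_module(self, module: RegulatorModule) -> list[GridEntry]:
        return [e for e in self.entries if e.config.module is module]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: module, algorithm, descriptor_set, split, metric, value."""
        rows = []
        for entry in self.entries:
            m, a, d = entry.config.key
            if entry.error is not None:
                rows.append(
                    {"module": m, "algorithm": a, "descriptor_set": d,
                     "split": "error", "metric": "error", "value": np.nan}
                )
                continue
            for metric in MetricsReport.METRIC_NAMES:
                rows.append(
                    {"module": m, "algorithm": a, "descriptor_set": d,
                     "split": "cv", "metric": metric, "value": entry.cv.mean[metric]}
                )
                rows.append(
                    {"module": m, "algorithm": a, "descriptor_set": d,
                     "split": "test", "metric": metric,
                     "value": getattr(entry.test, metric)}
                )
        return pd.DataFrame(rows)


def evaluate_grid(
    features: dict,
    labels: dict,
    configs: list[ModelConfig] | None = None,
    ratio: float = 0.8,
    folds: int = 10,
    seed: int = 0,
    splits: dict | None = None,
) -> GridResult:
    """Run the benchmarking grid.

    ``features`` maps (module, descriptor_set) to a FeatureMatrix or array;
    ``labels`` maps module to its 0/1 vector.  One stratified 4:1 split per
    module (derived from ``seed``) is shared across that module's configs.
    Per-config failures are recorded as error entries and the run continues.
    """
    modules = sorted(labels, key=lambda m: m.value)
    if configs is None:
        sets = sorted({d for (_, d) in features}, key=lambda d: d.value)
        configs = enumerate_grid(modules, list(Algorithm), sets, seed=seed)
    if splits is None:
        splits = {
            module: split_train_test(labels[module], ratio=ratio, seed=seed + i)
            for i, module in enumerate(modules)
        }
    entries = []
    for config in configs:
        module = config.module
        try:
            X = features[(module, config.descriptor_set)]
            if isinstance(X, FeatureMatrix):
                X = X.values
            y = np.asarray(labels[module], dtype=int)
            split = splits[module]
            X_train, y_train = X[split.train_indices], y[split.train_indices]
            X_test, y_test = X[split.test_indices], y[split.test_indices]
            cv = cross_validate(config, X_train, y_train, folds=folds)
            clf = train_classifier(config, X_train, y_train)
            test = evaluate_on(clf, X_test, y_test)
            entries.append(GridEntry(config=config, cv=cv, test=test))
        except Exception as exc:  # per-config failure must not kill the grid
            entries.append(GridEntry(config=config, error=f"{type(exc).__name__}: {exc}"))
    return GridResult(entries=entries)


_SELECTION_METRICS = ("ACC", "AUC", "F1", "MCC")


def _composite(entry: GridEntry) -> tuple:
    """Ranking key: mean of ACC/AUC/F1/MCC averaged over CV mean and test."""
    avg = {
        m: 0.5 * (entry.cv.mean[m] + getattr(entry.test, m)) for m in _SELECTION_METRICS
    }
    composite = float(np.mean([avg[m] for m in _SELECTION_METRICS]))
    return (composite, avg["MCC"], avg["AUC"])


def select_best(grid_result: GridResult, module: RegulatorModule) -> ModelConfig:
    """Pick the module's best config by composite metric, deterministic ties.

    Configs are ranked by the mean of (ACC, AUC, F1, MCC), each averaged over
    the CV mean and the external test value; ties break by MCC, then AUC,
    then enumeration order.
    """
    candidates = [e for e in grid_result.for_module(module) if e.error is None]
    if not candidates:
        raise ValueError(f"no successful grid entry for module {module.value}")
    best = max(
        enumerate(candidates), key=lambda ie: (_composite(ie[1]), -ie[0])
    )
    return best[1].config
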