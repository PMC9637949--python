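"""The algorithm x fingerprint benchmark grid.

Five classifier families (SVM with RBF kernel, Bernoulli naive Bayes,
k-nearest neighbours on Tanimoto distance, CART decision tree, random
forest) are crossed with the registered fingerprint schemes, each model
assessed by stratified 5-fold cross-validation and an external validation
set. Cross-validation pools the out-of-fold predictions into a single
confusion matrix (one ACC/SE/SP/MCC per model) and builds the ROC from
out-of-fold decision scores.

Hyperparameters: the SVM cost/kernel-width pair is grid-searched over
C in 2^-5..2^15 and gamma in 2^-15..2^3 (powers-of-4 steps), k over odd
1..21; the tree, forest and naive-Bayes models run with fixed declared
defaults (CART min leaf 2; 100 trees, sqrt(d) features; add-one smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .chemio import LabeledDataset
from .fingerprints import FingerprintMatrix, FingerprintTransformer, featurize_dataset
from .metrics import (
    MetricsReport,
    confusion_matrix_from_predictions,
    confusion_metrics,
    roc_auc,
)

__all__ = [
    "ALGORITHMS",
    "ModelConfig",
    "make_classifier",
    "decision_scores",
    "cross_validate",
    "tune_hyperparameters",
    "evaluate",
    "benchmark_grid",
    "select_best",
    "DiadClassifier",
]

# canonical names; table rows use e.g. MACCS_SVM, Estate_CT
ALGORITHMS = ("SVM", "NB", "kNN", "DT", "RF")
_ALIASES = {"SVM-RBF": "SVM", "CT": "DT", "TREE": "DT"}


def _canon_algorithm(name: str) -> str:
    n = _ALIASES.get(name, name)
    n = _ALIASES.get(n.upper(), n)
    for a in ALGORITHMS:
        if n.lower() == a.lower():
            return a
    raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    scheme: str = "MACCS"
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "algorithm", _canon_algorithm(self.algorithm))


_DEFAULT_HP = {
    "SVM": {"C": 1.0, "gamma": "scale"},
    "NB": {"alpha": 1.0},
    "kNN": {"n_neighbors": 5},
    "DT": {"min_samples_leaf": 2},
    "RF": {"n_estimators": 100, "max_features": "sqrt"},
}


def make_classifier(algorithm: str, hyperparameters: dict | None = None, seed: int = 0):
    """Instantiate the sklearn estimator behind one algorithm name."""
    algorithm = _canon_algorithm(algorithm)
    hp = dict(_DEFAULT_HP[algorithm])
    hp.update(hyperparameters or {})
    if algorithm == "SVM":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], random_state=seed)
    if algorithm == "NB":
        return BernoulliNB(alpha=hp["alpha"])
    if algorithm == "kNN":
        # Tanimoto similarity on binary bits == 1 - Jaccard distance;
        # score = positive-neighbour fraction via predict_proba
        return KNeighborsClassifier(n_neighbors=hp["n_neighbors"], metric="jaccard")
    if algorithm == "DT":
        return DecisionTreeClassifier(min_samples_leaf=hp["min_samples_leaf"],
                                      random_state=seed)
    return RandomForestClassifier(n_estimators=hp["n_estimators"],
                                  max_features=hp["max_features"], random_state=seed)


def _as_X(X) -> np.ndarray:
    if isinstance(X, FingerprintMatrix):
        X = X.bits
    X = np.asarray(X)
    return X.astype(bool) if X.dtype != bool else X


def decision_scores(model, X) -> np.ndarray:
    """Continuous scores for ROC: signed margin if available, else P(class 1)."""
    X = _as_X(X)
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return np.asarray(proba[:, pos_col], dtype=float)


def cross_validate(config: ModelConfig, X, y) -> MetricsReport:
    """Stratified k-fold CV with pooled out-of-fold scoring.

    Every record lands in exactly one test fold; predictions and decision
    scores are pooled across folds and scored once, so the report is a
    single confusion matrix plus an out-of-fold ROC/AUC. Deterministic in
    ``config.seed``.
    """
    X = _as_X(X)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    oof_pred = np.empty_like(y)
    oof_score = np.empty(len(y), dtype=float)
    base = make_classifier(config.algorithm, config.hyperparameters, config.seed)
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a CV fold lost a class; reduce folds or rebalance")
        model = clone(base)
        model.fit(X[train_idx], y[train_idx])
        oof_pred[test_idx] = model.predict(X[test_idx])
        oof_score[test_idx] = decision_scores(model, X[test_idx])
    report = confusion_metrics(confusion_matrix_from_predictions(y, oof_pred))
    report.roc, report.auc = roc_auc(y, oof_score)
    return report


_SVM_GRID = [
    {"C": 2.0 ** c, "gamma": 2.0 ** g}
    for c in range(-5, 16, 2)
    for g in range(-15, 4, 2)
]
_KNN_GRID = [{"n_neighbors": k} for k in range(1, 22, 2)]


def hyperparameter_grid(algorithm: str) -> list[dict]:
    algorithm = _canon_algorithm(algorithm)
    if algorithm == "SVM":
        return list(_SVM_GRID)
    if algorithm == "kNN":
        return list(_KNN_GRID)
    return []  # DT / RF / NB run with fixed declared defaults


def _fold_mean_accuracy(config: ModelConfig, X, y) -> float:
    X = _as_X(X)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    base = make_classifier(config.algorithm, config.hyperparameters, config.seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = clone(base)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def tune_hyperparameters(config: ModelConfig, X, y, grid: list[dict] | None = None) -> ModelConfig:
    """Grid search by mean 5-fold CV accuracy.

    Ties break toward the less complex model: smaller SVM cost (then smaller
    kernel width), larger k. Algorithms without a search grid return their
    fixed defaults unchanged; passing an explicitly empty grid is an error.
    """
    if grid is None:
        grid = hyperparameter_grid(config.algorithm)
        if not grid:
            return config
    if not grid:
        raise ValueError("empty hyperparameter grid")

    def complexity_key(hp: dict):
        if config.algorithm == "SVM":
            return (hp["C"], hp["gamma"])
        if config.algorithm == "kNN":
            return (-hp["n_neighbors"],)
        return (0,)

    scored = []
    for hp in grid:
        cand = replace(config, hyperparameters={**config.hyperparameters, **hp})
        scored.append((-_fold_mean_accuracy(cand, X, y), complexity_key(hp), hp))
    scored.sort(key=lambda t: (t[0], t[1]))
    best = scored[0][2]
    return replace(config, hyperparameters={**config.hyperparameters, **best})


def evaluate(model, X_valid, y_valid) -> MetricsReport:
    """Score a trained model on held-out data, with ROC/AUC from scores."""
    X_valid = _as_X(X_valid)
    y_valid = np.asarray(y_valid, dtype=int)
    pred = model.predict(X_valid)
    report = confusion_metrics(confusion_matrix_from_predictions(y_valid, pred))
    if len(np.unique(y_valid)) == 2:
        report.roc, report.auc = roc_auc(y_valid, decision_scores(model, X_valid))
    else:
        report.flags.append("single_class_validation")
    return report


def benchmark_grid(
    dataset: LabeledDataset,
    schemes: Sequence[str] = ("MACCS",),
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    cv_folds: int = 5,
    tune: bool = False,
) -> pd.DataFrame:
    """One CV-metrics row per (scheme, algorithm) combination.

    A failing combination is reported in its row's ``error`` column and the
    grid continues. Rows are named ``<scheme>_<algorithm>``.
    """
    y = dataset.labels()
    rows = []
    for scheme in schemes:
        scheme_name = getattr(scheme, "name", str(scheme))
        try:
            fpm = featurize_dataset(dataset, scheme)
        except Exception as exc:
            for algo in algorithms:
                rows.append({"Model": f"{scheme_name}_{_canon_algorithm(algo)}",
                             "error": str(exc)})
            continue
        for algo in algorithms:
            name = f"{scheme_name}_{_canon_algorithm(algo)}"
            try:
                config = ModelConfig(algo, scheme=scheme, cv_folds=cv_folds, seed=seed)
                if tune:
                    config = tune_hyperparameters(config, fpm, y)
                report = cross_validate(config, fpm, y)
                rows.append({"Model": name, **report.as_row(),
                             "hyperparameters": config.hyperparameters, "error": ""})
            except Exception as exc:
                rows.append({"Model": name, "error": str(exc)})
    return pd.DataFrame(rows)


def select_best(table: pd.DataFrame) -> str:
    """Best benchmark row by ACC, ties broken by MCC."""
    ok = table[table.get("error", "") == ""].copy()
    if ok.empty:
        raise ValueError("no successful benchmark rows")
    ok = ok.sort_values(["ACC", "MCC"], ascending=False, kind="mergesort")
    return str(ok.iloc[0]["Model"])


class DiadClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end DIAD classifier: SMILES in, label and score out.

    Composes a :class:`FingerprintTransformer` with one of the benchmark
    algorithms; the default (MACCS keys + RBF-kernel SVM) is the
    best-performing published combination.

    Parameters
    ----------
    scheme : fingerprint scheme name (default "MACCS")
    algorithm : one of SVM, NB, kNN, DT, RF (default "SVM")
    hyperparameters : overrides for the algorithm's defaults
    tune : grid-search hyperparameters on fit (SVM/kNN only)
    seed : controls folding and any stochastic learner
    """

    def __init__(self, scheme="MACCS", algorithm="SVM", hyperparameters=None,
                 tune=False, cv_folds=5, seed=0):
        self.scheme = scheme
        self.algorithm = algorithm
        self.hyperparameters = hyperparameters
        self.tune = tune
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y):
        """Fit on a sequence of SMILES (or Mols) and binary labels."""
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.transformer_ = FingerprintTransformer(self.scheme).fit(X)
        bits = self.transformer_.transform(X)
        config = ModelConfig(self.algorithm, scheme=str(self.scheme),
                             hyperparameters=dict(self.hyperparameters or {}),
                             cv_folds=self.cv_folds, seed=self.seed)
        if self.tune:
            config = tune_hyperparameters(config, bits, y)
        self.config_ = config
        self.model_ = make_classifier(config.algorithm, config.hyperparameters,
                                      config.seed)
        self.model_.fit(_as_X(bits), y)
        self.classes_ = np.asarray([0, 1])
        self.cv_report_ = cross_validate(config, bits, y)
        return self

    def _bits(self, X):
        check_is_fitted(self, "model_")
        return _as_X(self.transformer_.transform(X))

    def predict(self, X):
        return self.model_.predict(self._bits(X))

    def decision_function(self, X):
        return decision_scores(self.model_, self._bits(X))

    def score_table(self, ids, X) -> pd.DataFrame:
        bits = self._bits(X)
        return pd.DataFrame({
            "id": list(ids),
            "label": self.model_.predict(bits).astype(int),
            "score": decision_scores(self.model_, bits),
        })
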