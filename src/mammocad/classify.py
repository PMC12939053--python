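"""Soft-margin RBF-SVM training, prediction, and hyperparameter grid search.

Features are z-scored with statistics fitted on the training data only —
the RBF kernel measures Euclidean distances, so unscaled feature blocks
(e.g. region area vs. a probability-valued texture statistic) would
otherwise dominate the kernel.  The penalty parameter C and the kernel
width gamma are tuned by exhaustive search over the candidate set
{0.0001, 0.001, 0.01, 0.1, 1, 10, 100} using seeded stratified 5-fold CV
accuracy, with deterministic tie-breaking (smaller C, then smaller gamma).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable, SchemaError
from .select import FeatureSubset

DEFAULT_GRID: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class SVMConfig:
    c: float = 1.0
    gamma: float | str = "scale"
    grid: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not self.grid:
            raise ValueError("grid must be non-empty")


@dataclass
class TrainedClassifier:
    """A fitted scaler + SVC pair bound to the feature names it was trained on."""

    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svc: SVC
    config: SVMConfig

    def decision_values(self, table: FeatureTable) -> np.ndarray:
        x = _column_block(table, self.feature_names)
        return self.svc.decision_function((x - self.scaler_mean) / self.scaler_scale)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "c": self.config.c,
            "gamma": self.config.gamma,
            "gamma_value": float(self.svc._gamma),
            "support_vectors": self.svc.support_vectors_.tolist(),
            "dual_coef": self.svc.dual_coef_.tolist(),
            "intercept": self.svc.intercept_.tolist(),
            "classes": self.svc.classes_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _column_block(table: FeatureTable, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in table.feature_names]
    if missing:
        raise SchemaError(f"table is missing feature columns: {missing[:5]}")
    index = [table.feature_names.index(n) for n in names]
    return table.values[:, index]


def train_svm(
    table: FeatureTable,
    subset: Optional[FeatureSubset] = None,
    config: SVMConfig = SVMConfig(),
) -> TrainedClassifier:
    """Fit scaler + soft-margin RBF-SVM on the subset columns (all if None)."""
    if len(np.unique(table.labels)) < 2:
        raise ValueError("training requires both classes present")
    indices = list(subset.indices) if subset is not None else list(range(table.n_features))
    names = [table.feature_names[i] for i in indices]
    x = table.values[:, indices]
    scaler = StandardScaler().fit(x)
    svc = SVC(kernel="rbf", C=config.c, gamma=config.gamma)
    svc.fit(scaler.transform(x), table.labels)
    return TrainedClassifier(names, scaler.mean_, scaler.scale_, svc, config)


def predict_labels(model: TrainedClassifier, table: FeatureTable) -> np.ndarray:
    """Binary label per sample, applying the stored standardization."""
    x = _column_block(table, model.feature_names)
    return model.svc.predict((x - model.scaler_mean) / model.scaler_scale)


@dataclass
class GridSearchResult:
    best: SVMConfig
    scores: pd.DataFrame = field(repr=False)


def grid_search_hyperparams(
    table: FeatureTable,
    subset: Optional[FeatureSubset] = None,
    config: SVMConfig = SVMConfig(),
    seed: int = 0,
    cv_folds: int = 5,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search over grid x grid by stratified CV accuracy.

    Standardization is refitted inside each training fold.  Ties break
    toward smaller C, then smaller gamma, so the winner is deterministic for
    a given seed.
    """
    indices = list(subset.indices) if subset is not None else list(range(table.n_features))
    x = table.values[:, indices]
    y = table.labels
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    rows = []
    for c in sorted(config.grid):
        for gamma in sorted(config.grid):
            accs = []
            for train_idx, test_idx in splits:
                scaler = StandardScaler().fit(x[train_idx])
                clf = SVC(kernel="rbf", C=c, gamma=gamma)
                clf.fit(scaler.transform(x[train_idx]), y[train_idx])
                accs.append(clf.score(scaler.transform(x[test_idx]), y[test_idx]))
            rows.append(dict(c=c, gamma=gamma, cv_accuracy=float(np.mean(accs))))
    scores = pd.DataFrame(rows)
    # stable ordering already iterates smaller c then smaller gamma first
    winner = scores.loc[scores["cv_accuracy"].idxmax()]
    best = replace(config, c=float(winner["c"]), gamma=float(winner["gamma"]))
    return GridSearchResult(best, scores)
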