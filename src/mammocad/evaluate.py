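"""Stratified k-fold evaluation: confusion matrices, metrics, aggregation.

The malignant class is the positive class throughout.  Reported metrics are
percentages: accuracy, sensitivity (true-positive rate over malignant
cases), specificity (true-negative rate over benign cases), and F1.

Two F1 variants are provided.  ``precision_recall`` is the standard
harmonic mean of precision and recall.  ``sensitivity_specificity`` is the
harmonic mean of sensitivity and specificity; published mammography-CAD
evaluation tables are sometimes internally consistent only under this
variant (see docs/methods.md), so it is available for exact reproduction of
such reference aggregates.  Fold aggregation uses the arithmetic mean and
the sample (n-1) standard deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .classify import GridSearchResult, SVMConfig, grid_search_hyperparams, predict_labels, train_svm
from .io import FeatureTable, warn_degenerate
from .select import FeatureSubset, ISAConfig, run_classic_sa, run_isa


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return dict(accuracy=self.accuracy, sensitivity=self.sensitivity,
                    specificity=self.specificity, f1=self.f1)


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1")


def build_confusion(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    positive_label: int = 1,
) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with the malignant (1) class as positive."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    negative = 1 - positive_label
    cm = _sk_confusion(y_true, y_pred, labels=[positive_label, negative])
    return ConfusionMatrix(tp=int(cm[0, 0]), fn=int(cm[0, 1]),
                           fp=int(cm[1, 0]), tn=int(cm[1, 1]))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warn_degenerate(f"{name}: 0/0 denominator, defining the metric as 0")
        return 0.0
    return 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix, f1_mode: str = "precision_recall") -> MetricSet:
    """Percent accuracy, sensitivity, specificity and F1 from raw counts.

    Any 0/0 denominator yields a defined 0 (with a runtime warning).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if f1_mode == "precision_recall":
        precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
        a, b = precision, sensitivity
    elif f1_mode == "sensitivity_specificity":
        a, b = sensitivity, specificity
    else:
        raise ValueError(f"unknown f1_mode {f1_mode!r}")
    if a + b == 0:
        warn_degenerate("f1: 0/0 denominator, defining the metric as 0")
        f1 = 0.0
    else:
        f1 = 2.0 * a * b / (a + b)
    return MetricSet(accuracy, sensitivity, specificity, f1)


def stratified_kfold_split(
    table: FeatureTable, k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Seeded stratified partition into k test folds (per-class counts +-1)."""
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(table.values, table.labels)]


def aggregate_metrics(
    per_fold: Sequence[MetricSet],
) -> dict[str, tuple[float, float]]:
    """Mean and sample (n-1) std of each metric across folds."""
    if len(per_fold) < 2:
        raise ValueError("aggregation needs >= 2 folds")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


@dataclass
class CVSummary:
    """Per-fold confusion matrices/metrics and their mean/std aggregates."""

    confusions: list[ConfusionMatrix]
    metrics: list[MetricSet]
    summary: dict[str, tuple[float, float]]
    selected: list[Optional[FeatureSubset]] = field(default_factory=list)
    svm_configs: list[SVMConfig] = field(default_factory=list)


def cross_validate_pipeline(
    table: FeatureTable,
    selector: str = "none",
    k: int = 5,
    seed: int = 0,
    isa_config: Optional[ISAConfig] = None,
    svm_config: SVMConfig = SVMConfig(),
    grid_search: bool = True,
    nf_fixed: Optional[int] = None,
    selection_scope: str = "per_fold",
    f1_mode: str = "precision_recall",
) -> CVSummary:
    """Full evaluation loop: selection + tuning on training partitions only.

    ``selector`` is ``"isa"``, ``"sa"`` (fixed size, requires ``nf_fixed``)
    or ``"none"`` (all features).  With ``selection_scope="per_fold"``
    (default, leakage-safe) selection is re-run inside every fold; with
    ``"global"`` it runs once on the full table before splitting.
    """
    if selector not in ("isa", "sa", "none"):
        raise ValueError(f"unknown selector {selector!r}")
    if selector == "sa" and nf_fixed is None:
        raise ValueError("selector 'sa' requires nf_fixed")
    if selection_scope not in ("per_fold", "global"):
        raise ValueError(f"unknown selection_scope {selection_scope!r}")
    isa_config = isa_config or ISAConfig(seed=seed)

    def select(train_table: FeatureTable, fold_seed: int) -> Optional[FeatureSubset]:
        cfg = dataclasses.replace(isa_config, seed=fold_seed)
        if selector == "isa":
            return run_isa(train_table, cfg).subset
        if selector == "sa":
            return run_classic_sa(train_table, nf_fixed, cfg).subset
        return None

    global_subset = select(table, seed) if selection_scope == "global" else None

    folds = stratified_kfold_split(table, k, seed)
    all_idx = np.arange(table.n_samples)
    confusions, metrics, selected, configs = [], [], [], []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_table = table.select_rows(train_idx)
        test_table = table.select_rows(test_idx)
        if selection_scope == "global":
            subset = global_subset
        else:
            subset = select(train_table, seed + fold_no)
        cfg = svm_config
        if grid_search:
            cfg = grid_search_hyperparams(train_table, subset, svm_config, seed).best
        model = train_svm(train_table, subset, cfg)
        cm = build_confusion(test_table.labels, predict_labels(model, test_table))
        confusions.append(cm)
        metrics.append(compute_metrics(cm, f1_mode))
        selected.append(subset)
        configs.append(cfg)
    return CVSummary(confusions, metrics, aggregate_metrics(metrics), selected, configs)
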