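"""Published per-fold confusion matrices for the two mammography cohorts.

These are the fold-level evaluation counts reported for RBF-SVM
classification on the MIAS (20-image test folds, 10 per class) and
CBIS-DDSM (60-image test folds, 30 per class) cohorts under three feature
regimes: the dynamic-length annealing selector (ISA), the fixed-size
annealing baseline (SA), and the full 104-feature set.  They serve as
inputs for validating the metric and aggregation code: feeding them through
:func:`mammocad.evaluate.compute_metrics` and
:func:`mammocad.evaluate.aggregate_metrics` must reproduce the reference
mean/std summary table.

Matrices are ``(TP, FN, FP, TN)`` with malignant as the positive class.
"""

from __future__ import annotations

from .evaluate import ConfusionMatrix, aggregate_metrics, compute_metrics

REFERENCE_FOLD_MATRICES: dict[str, dict[str, list[tuple[int, int, int, int]]]] = {
    "mias": {
        "isa": [
            (10, 0, 0, 10),
            (10, 0, 0, 10),
            (10, 0, 0, 10),
            (9, 1, 0, 10),
            (10, 0, 1, 9),
        ],
        "sa": [
            (8, 2, 0, 10),
            (8, 2, 0, 10),
            (10, 0, 0, 10),
            (10, 0, 0, 10),
            (8, 2, 0, 10),
        ],
        "all_features": [
            (7, 3, 1, 9),
            (7, 3, 0, 10),
            (7, 3, 1, 9),
            (9, 1, 0, 10),
            (8, 2, 1, 9),
        ],
    },
    "cbis_ddsm": {
        "isa": [
            (30, 0, 0, 30),
            (30, 0, 0, 30),
            (30, 0, 0, 30),
            (29, 1, 0, 30),
            (30, 0, 0, 30),
        ],
        "sa": [
            (28, 2, 1, 29),
            (27, 3, 0, 30),
            (28, 2, 2, 28),
            (29, 1, 0, 30),
            (30, 0, 1, 29),
        ],
        "all_features": [
            (25, 5, 5, 25),
            (28, 2, 0, 30),
            (25, 5, 5, 25),
            (30, 0, 5, 25),
            (24, 6, 5, 25),
        ],
    },
}

#: number of features the selectors retained in the reference runs
REFERENCE_SELECTED_COUNTS = {"mias": 34, "cbis_ddsm": 31}


def reference_confusions(dataset: str, method: str) -> list[ConfusionMatrix]:
    rows = REFERENCE_FOLD_MATRICES[dataset][method]
    return [ConfusionMatrix(*row) for row in rows]


def reproduce_reference_summary(
    f1_mode: str = "sensitivity_specificity",
) -> dict[str, dict[str, dict[str, tuple[float, float]]]]:
    """Recompute the mean/std summary for every cohort and feature regime.

    The default ``f1_mode`` is the variant under which the published
    aggregate table is internally consistent with its own fold matrices
    (harmonic mean of sensitivity and specificity; see docs/methods.md).
    """
    out: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for dataset, methods in REFERENCE_FOLD_MATRICES.items():
        out[dataset] = {}
        for method in methods:
            metrics = [
                compute_metrics(cm, f1_mode)
                for cm in reference_confusions(dataset, method)
            ]
            out[dataset][method] = aggregate_metrics(metrics)
    return out
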