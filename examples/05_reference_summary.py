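"""Recompute the published cohort summary from its per-fold counts.

The package bundles the published fold-level confusion matrices for the
MIAS and CBIS-DDSM evaluation cohorts (5 folds x 3 feature regimes each).
Running them through compute_metrics + aggregate_metrics reproduces the
published mean/std summary table.
"""

from mammocad.evaluate import aggregate_metrics, compute_metrics
from mammocad.reference import REFERENCE_FOLD_MATRICES, reference_confusions

for dataset in REFERENCE_FOLD_MATRICES:
    print(f"\n{dataset} cohort:")
    for method in REFERENCE_FOLD_MATRICES[dataset]:
        metrics = [compute_metrics(cm, f1_mode="sensitivity_specificity")
                   for cm in reference_confusions(dataset, method)]
        summary = aggregate_metrics(metrics)
        cells = "  ".join(f"{name} {mean:6.2f}+-{std:5.2f}"
                          for name, (mean, std) in summary.items())
        print(f"  {method:13s} {cells}")

print("\nNote: the published aggregate F1 row is consistent with the "
      "harmonic mean of sensitivity and specificity, which is what "
      "f1_mode='sensitivity_specificity' computes; the default "
      "'precision_recall' mode gives the textbook F1 instead.")
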