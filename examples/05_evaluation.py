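"""Evaluation harness: fold aggregation, ROC/AUC, abstention analysis.

Shows the half-up fold aggregation on a published-style nine-fold metric
table, the trapezoidal AUC against scores, and selective prediction:
accuracy among samples retained at an entropy cutoff.
"""

import numpy as np
import pandas as pd

import dropweak as dw

# a nine-fold metric table (percent); the Average row is recomputed
rows = pd.DataFrame(
    {
        "sensitivity": [90.47, 84.56, 95.28, 98.82, 82.13, 94.38, 89.97, 89.75, 96.56],
        "precision": [88.43, 89.29, 90.15, 91.68, 80.46, 89.44, 82.89, 85.69, 88.47],
        "accuracy": [88.78, 88.57, 91.41, 97.19, 91.78, 96.55, 87.38, 86.94, 85.36],
        "specificity": [89.57, 87.49, 85.88, 92.56, 85.98, 89.47, 94.86, 90.67, 89.85],
        "f1": [91.15, 89.92, 84.56, 97.47, 85.16, 98.28, 82.74, 80.34, 81.38],
    }
)
print("aggregate (half-up, 2 decimals):", dw.aggregate_folds(rows))

# ROC on a toy malignancy-score vector (roughly calibrated: scores near
# 0 or 1 are usually right, scores near 0.5 are coin flips)
rng = np.random.default_rng(0)
labels = rng.integers(0, 2, 200)
scores = np.clip(np.where(labels == 1, 0.8, 0.2) + rng.normal(0, 0.15, 200), 0.01, 0.99)
points, auc = dw.roc_auc(scores, labels)
print(f"AUC over 200 scored samples: {auc:.4f} ({len(points)} ROC points)")

# abstention: retain only low-entropy predictions
pred_mean = np.stack([1 - scores, scores], axis=1)
entropies = np.asarray(dw.entropy(pred_mean))
for thr, frac, acc in dw.uncertainty_accuracy_analysis(pred_mean, entropies, labels, [0.3, 0.5]):
    print(f"entropy <= {thr}: retained {frac:.2%}, accuracy of retained {acc:.2%}")
print("stricter cutoffs keep fewer, more confidently-classified samples.")
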