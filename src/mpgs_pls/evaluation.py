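"""ROC/AUC of the first latent variable used as a classifier score.

The first PLS component score t1 orders subjects along the fitted predictive
direction; sweeping a cutpoint over it yields sensitivity/specificity pairs
and the area under the ROC curve.  The AUC is computed by trapezoidal
integration of the curve, which equals the Mann-Whitney pairwise-concordance
probability with ties counted 1/2.  Scores are oriented so that cases tend
to score higher (AUC >= 0.5); whether a flip was applied is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .datatypes import AnalysisError
from .pls import PLSModel


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # true-positive rate per threshold
    specificity: np.ndarray  # true-negative rate per threshold
    auc: float
    flipped: bool  # True if scores were negated to orient cases higher

    def points_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_from_scores(scores: np.ndarray, y: np.ndarray, orient: bool = True) -> ROCResult:
    """ROC curve and trapezoidal AUC for a continuous score vs 0/1 labels."""
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if np.unique(y).size < 2:
        raise AnalysisError("ROC needs both outcome classes")
    flipped = False
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    if orient and auc < 0.5:
        flipped = True
        fpr, tpr, thr = roc_curve(y, -scores)
        auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc, flipped=flipped
    )


def roc_first_latent(model: PLSModel, X: np.ndarray, y: np.ndarray) -> ROCResult:
    """ROC of the first latent variable evaluated on (original-scale) X."""
    t1 = model.transform(X)[:, 0]
    return roc_from_scores(t1, y)


def concordance_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Pairwise-concordance AUC (Mann-Whitney, ties = 1/2).

    O(n_cases * n_controls) brute force; used as the dual route to the
    trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel()
    cases = scores[y == 1]
    controls = scores[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise AnalysisError("concordance needs both outcome classes")
    gt = (cases[:, None] > controls[None, :]).sum()
    eq = (cases[:, None] == controls[None, :]).sum()
    return float((gt + 0.5 * eq) / (cases.size * controls.size))
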