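"""Subject-level OR risk scoring, ROC analysis and Youden cutoff selection.

Each subject is assigned the odds ratio of the highest-priority barcode
model it matches as exposed (models are supplied in priority order, e.g. a
nested family from highest order down); subjects matching no model — or
excluded from every model by missingness — carry the reference score 1.0.
The ROC sweeps thresholds over the scores with OPMD and cancer pooled as
"case"; the operating cutoff maximises Youden's J = sensitivity +
specificity - 1, with ties resolved toward the higher-specificity (higher)
threshold, and a score >= cutoff is called high risk.

The per-subject scoring construction is a reconstruction of the published
analysis style, not a reproduction of an exactly specified procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .barcode import Barcode, match_subject, EXPOSED
from .cohort import Cohort, FactorDefinition
from .stats import TwoByTwo, apply_haldane, odds_ratio


@dataclass(frozen=True)
class RocResult:
    """ROC sweep with the Youden-optimal operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def pooled_case_or(cohort: Cohort, barcode: Barcode) -> float:
    """Odds ratio of a barcode with OPMD+cancer pooled against controls.

    Haldane-corrected when a zero cell occurs, so the score is finite for
    any barcode with at least one usable subject per arm.
    """
    from .barcode import CohortEvaluator

    ev = CohortEvaluator(cohort).evaluate(barcode)
    if ev.table_cvn is None or ev.table_pvn is None:
        return float("nan")
    pooled = TwoByTwo(
        d_e=ev.table_cvn.d_e + ev.table_pvn.d_e,
        h_e=ev.table_cvn.h_e,
        d_n=ev.table_cvn.d_n + ev.table_pvn.d_n,
        h_n=ev.table_cvn.h_n,
    )
    return odds_ratio(apply_haldane(pooled))


def score_subjects(
    cohort: Cohort, models: Sequence[tuple[Barcode, float]]
) -> pd.DataFrame:
    """Assign each subject the OR of the first model it matches as exposed.

    ``models`` is a priority-ordered list of (barcode, score OR).  Returns a
    frame with columns ``label`` (1 = case: OPMD or cancer, 0 = control),
    ``score``, ``model`` (matched model index or -1) and ``flagged`` (True
    when the subject was excluded by missingness from every model).
    """
    if not models:
        raise ValueError("at least one model is required")
    for _, score in models:
        if not np.isfinite(score) or score < 0:
            raise ValueError("model scores must be finite non-negative odds ratios")
    labels = (cohort.data["group"] != "control").to_numpy().astype(int)
    scores = np.ones(cohort.n_subjects)
    matched = np.full(cohort.n_subjects, -1)
    any_usable = np.zeros(cohort.n_subjects, dtype=bool)
    for j, (bc, score) in enumerate(models):
        statuses = np.array(
            [match_subject(row, bc) for row in cohort.data[cohort.factor_names].to_dict("records")]
        )
        hit = (statuses == EXPOSED) & (matched == -1)
        scores[hit] = score
        matched[hit] = j
        any_usable |= statuses != "excluded"
    return pd.DataFrame(
        {
            "label": labels,
            "score": scores,
            "model": matched,
            "flagged": ~any_usable,
        },
        index=cohort.data.index,
    )


def roc_from_scores(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    """ROC curve, trapezoidal AUC and Youden-optimal cutoff.

    ``labels`` are 1 for case, 0 for control; both must be present.  Ties in
    Youden's J pick the higher threshold (higher specificity); the returned
    cutoff classifies score >= cutoff as high risk.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC needs both case and control labels")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    area = float(_trapezoid_auc(fpr, tpr))
    j = tpr - fpr
    # thresholds are in decreasing order, so the first argmax is the
    # highest-threshold (highest-specificity) tie.
    idx = int(np.argmax(j))
    cutoff = float(thresholds[idx])
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=area,
        cutoff=cutoff,
        sensitivity=float(tpr[idx]),
        specificity=float(1.0 - fpr[idx]),
    )


def classify(
    labels: np.ndarray, scores: np.ndarray, cutoff: float
) -> dict[str, float]:
    """High/low-risk partition at a cutoff (high iff score >= cutoff).

    Returns the confusion counts (tp/fp/tn/fn) plus sensitivity and
    specificity.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    labels = np.asarray(labels).astype(bool)
    high = np.asarray(scores, dtype=float) >= cutoff
    tp = int(np.sum(high & labels))
    fp = int(np.sum(high & ~labels))
    fn = int(np.sum(~high & labels))
    tn = int(np.sum(~high & ~labels))
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


class OddsRatioRiskClassifier(BaseEstimator, ClassifierMixin):
    """Barcode-family risk classifier with a Youden-selected OR cutoff.

    Given a priority-ordered family of barcode models, ``fit`` computes each
    model's pooled-case odds ratio on the training cohort, scores every
    subject, sweeps the ROC with cases = OPMD+cancer, and fixes the
    operating cutoff at the maximum of Youden's J.  ``predict`` labels new
    subjects high risk (1) when their score reaches the cutoff.

    Parameters
    ----------
    models : sequence of Barcode
        Priority order: the first matching model supplies the score.
    alpha : float
        Significance level carried through to the per-model estimates.

    Attributes
    ----------
    model_scores_ : list of (Barcode, pooled OR) used for scoring.
    roc_ : RocResult on the training cohort.
    auc_, cutoff_, sensitivity_, specificity_ : operating summary.
    """

    def __init__(self, models: Sequence[Barcode] = (), alpha: float = 0.05):
        self.models = models
        self.alpha = alpha

    def fit(self, X, y=None, factors: Sequence[FactorDefinition] | None = None):
        if not self.models:
            raise ValueError("at least one barcode model is required")
        cohort = X if isinstance(X, Cohort) else Cohort.from_arrays(X, y, factors=factors)
        self.model_scores_ = [(bc, pooled_case_or(cohort, bc)) for bc in self.models]
        bad = [str(bc) for bc, s in self.model_scores_ if not np.isfinite(s)]
        if bad:
            raise ValueError(f"models with undefined pooled OR: {bad}")
        self.factors_ = cohort.factors
        scored = score_subjects(cohort, self.model_scores_)
        self.roc_ = roc_from_scores(scored["label"].to_numpy(), scored["score"].to_numpy())
        self.auc_ = self.roc_.auc
        self.cutoff_ = self.roc_.cutoff
        self.sensitivity_ = self.roc_.sensitivity
        self.specificity_ = self.roc_.specificity
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X, y=None) -> np.ndarray:
        cohort = X if isinstance(X, Cohort) else Cohort.from_arrays(
            X, ["control"] * len(X), factors=self.factors_
        )
        return score_subjects(cohort, self.model_scores_)["score"].to_numpy()

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.cutoff_).astype(int)
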