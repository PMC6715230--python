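"""Fitness of a barcode evaluation: sigmoid-weighted joint odds ratios.

The search objective rewards a combination that (a) carries high odds ratios
in both the cancer-vs-control and OPMD-vs-control comparisons, (b) separates
the two case groups (a large cancer-minus-OPMD OR difference), and (c) is
jointly significant in both comparisons:

    f = S(OR_CvN) + S(OR_PvN) + S(OR_CvN - OR_PvN) + p

with S the logistic sigmoid and p = 1 iff both Pearson chi-square p-values
fall below alpha (0.05 by default), else 0.  Defined fitness therefore lies
in (0, 4).  An undefined evaluation (a comparison group with no usable
subjects, or an undefined OR) maps to the sentinel -inf so it can never
become a personal or global best.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

#: Sentinel fitness for undefined/empty/over-cap evaluations.
UNDEFINED_FITNESS = -math.inf


def sigmoid(v):
    """Logistic sigmoid 1/(1+exp(-v)), elementwise."""
    return expit(v)


def fitness(evaluation, alpha: float = 0.05) -> float:
    """Eq-style OR fitness of a :class:`~snpbarcode.barcode.BarcodeEvaluation`.

    Returns :data:`UNDEFINED_FITNESS` when the evaluation is undefined or
    either OR is not finite.
    """
    if evaluation is None or not getattr(evaluation, "defined", False):
        return UNDEFINED_FITNESS
    or_c = evaluation.est_cvn.or_value
    or_p = evaluation.est_pvn.or_value
    if not (np.isfinite(or_c) and np.isfinite(or_p)):
        return UNDEFINED_FITNESS
    p_c = evaluation.est_cvn.p_value
    p_p = evaluation.est_pvn.p_value
    significant = bool(p_c < alpha) and bool(p_p < alpha)  # NaN compares False
    return float(expit(or_c) + expit(or_p) + expit(or_c - or_p) + (1.0 if significant else 0.0))
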