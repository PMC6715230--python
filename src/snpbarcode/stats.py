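"""Contingency-table risk statistics for case-control exposure analysis.

The unit of analysis is a 2x2 table of exposed/unexposed by diseased/healthy
counts.  All effect estimates are crude (unadjusted) odds ratios with Woolf
(logit-scale) confidence intervals; significance comes from the plain Pearson
chi-square on the raw counts, with no continuity correction.  Tables with a
zero cell are stabilised for the OR/CI only via the Haldane-Anscombe +0.5
correction; the chi-square always sees the raw counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import chdtrc, ndtri

__all__ = [
    "TwoByTwo",
    "RiskEstimate",
    "apply_haldane",
    "odds_ratio",
    "woolf_ci",
    "pearson_chi2",
    "risk_estimate",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed/unexposed x diseased/healthy contingency table.

    Parameters
    ----------
    d_e : float
        Exposed subjects with disease.
    h_e : float
        Exposed healthy subjects.
    d_n : float
        Unexposed subjects with disease.
    h_n : float
        Unexposed healthy subjects.

    Cells are non-negative; fractional cells arise only from the
    Haldane-Anscombe correction.
    """

    d_e: float
    h_e: float
    d_n: float
    h_n: float

    def __post_init__(self) -> None:
        cells = (self.d_e, self.h_e, self.d_n, self.h_n)
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cell in 2x2 table: {cells}")
        if sum(cells) <= 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> float:
        return self.d_e + self.h_e + self.d_n + self.h_n

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.d_e, self.h_e, self.d_n, self.h_n)


@dataclass(frozen=True)
class RiskEstimate:
    """Odds ratio with Woolf CI and Pearson chi-square significance.

    ``or_value``/``ci_low``/``ci_high`` may be ``nan`` when undefined
    (e.g. a zero denominator with the zero-cell policy disabled);
    ``chi2``/``p_value`` are ``nan`` when a table margin is zero.
    """

    or_value: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float


def apply_haldane(table: TwoByTwo) -> TwoByTwo:
    """Haldane-Anscombe zero-cell correction.

    If any cell is zero, add 0.5 to all four cells; otherwise return the
    table unchanged.
    """
    if min(table.cells) == 0:
        return TwoByTwo(*(c + 0.5 for c in table.cells))
    return table


def odds_ratio(table: TwoByTwo) -> float:
    """Crude odds ratio D_E*H_N / (H_E*D_N); ``nan`` on a zero denominator."""
    denom = table.h_e * table.d_n
    if denom == 0:
        return math.nan
    return (table.d_e * table.h_n) / denom


def woolf_ci(table: TwoByTwo, alpha: float = 0.05) -> tuple[float, float]:
    """Woolf logit-scale (1-alpha) confidence interval for the odds ratio.

    exp( ln OR +- z_{1-alpha/2} * sqrt(1/D_E + 1/H_E + 1/D_N + 1/H_N) ).
    Any zero cell makes the interval undefined (``nan`` bounds); apply
    :func:`apply_haldane` first if a finite interval is required.
    """
    if min(table.cells) == 0:
        return (math.nan, math.nan)
    or_value = odds_ratio(table)
    z = ndtri(1.0 - alpha / 2.0)
    se = math.sqrt(sum(1.0 / c for c in table.cells))
    log_or = math.log(or_value)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def pearson_chi2(table: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p-value at 1 df.

    Computed with the 2x2 shortcut N*(ad-bc)^2 / (row and column margin
    product), which is algebraically identical to the sum of
    (observed-expected)^2/expected over the four cells.  No continuity
    correction.  A zero margin makes the statistic undefined (``nan``).
    """
    a, b, c, d = table.cells
    n = a + b + c + d
    m_dis = a + c
    m_hea = b + d
    m_exp = a + b
    m_une = c + d
    denom = m_dis * m_hea * m_exp * m_une
    if denom == 0:
        return (math.nan, math.nan)
    stat = n * (a * d - b * c) ** 2 / denom
    return (stat, float(chdtrc(1, stat)))


def risk_estimate(table: TwoByTwo, alpha: float = 0.05) -> RiskEstimate:
    """Full risk summary of a raw-count table.

    OR and CI are computed on the Haldane-corrected table (correction applied
    only when a zero cell is present); the chi-square and its p-value use the
    raw counts.
    """
    corrected = apply_haldane(table)
    or_value = odds_ratio(corrected)
    ci_low, ci_high = woolf_ci(corrected, alpha=alpha)
    chi2, p_value = pearson_chi2(table)
    return RiskEstimate(or_value, ci_low, ci_high, chi2, p_value)
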