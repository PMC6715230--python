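"""Barcodes: factor-level combinations treated as a single exposure.

A barcode is an ordered set of (factor name, level code) selections, e.g.
age>50 AND rs887844=A/G, written "2-1" in reports.  A subject is *exposed*
if it matches every selected level, *unexposed* ("other") if it differs on
at least one fully observed selected factor, and *excluded* (listwise, per
barcode) if any selected factor is missing.  Evaluating a barcode builds two
2x2 tables against the shared control group — cancer-vs-control and
OPMD-vs-control — and summarises both with odds ratios, Woolf intervals and
Pearson chi-square p-values.

Particles of the binary swarm encode a barcode with two bits per factor:
(0,0) leaves the factor unselected; (0,1), (1,0), (1,1) select it in status
1, 2 or 3.  Status s selects level code s-1, so status 1 can reach the code-0
category (e.g. alcohol non-drinkers, barcode "2-0").  A status that maps to
a code outside the factor's valid codes leaves the factor unselected, so
every bit pattern decodes to a feasible (possibly empty) barcode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, FactorDefinition
from .objective import UNDEFINED_FITNESS, fitness as _fitness
from .stats import RiskEstimate, TwoByTwo, risk_estimate

EXPOSED = "exposed"
UNEXPOSED = "unexposed"
EXCLUDED = "excluded"

EMPTY_LABEL = "∅"  # ∅

_NAN_ESTIMATE = RiskEstimate(*(float("nan"),) * 5)


@dataclass(frozen=True)
class Barcode:
    """Ordered (factor name, level code) selections."""

    selections: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.selections]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factors in barcode: {names}")
        object.__setattr__(
            self, "selections", tuple((str(n), int(c)) for n, c in self.selections)
        )

    @property
    def order(self) -> int:
        return len(self.selections)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.selections)

    def level(self, name: str) -> int:
        for n, c in self.selections:
            if n == name:
                return c
        raise KeyError(name)

    def __str__(self) -> str:
        return format_barcode(self)


def format_barcode(barcode: Barcode, factor_order: Sequence[str] | None = None) -> str:
    """Level codes joined by '-', in cohort schema order when given.

    The empty barcode renders as '∅'.
    """
    if barcode.order == 0:
        return EMPTY_LABEL
    sel = dict(barcode.selections)
    if factor_order is not None:
        names = [n for n in factor_order if n in sel]
        if len(names) != barcode.order:
            missing = set(sel) - set(names)
            raise KeyError(f"barcode factors not in factor order: {sorted(missing)}")
    else:
        names = list(barcode.factor_names)
    return "-".join(str(sel[n]) for n in names)


def model_label(barcode: Barcode, factor_order: Sequence[str] | None = None) -> str:
    """Comma-joined factor names, in schema order when given."""
    if barcode.order == 0:
        return EMPTY_LABEL
    names = list(barcode.factor_names)
    if factor_order is not None:
        names = [n for n in factor_order if n in names]
    return ",".join(names)


def decode_particle(position: Sequence[int], factors: Sequence[FactorDefinition]) -> Barcode:
    """Decode a 2-bits-per-factor binary position into a barcode.

    ``position`` has length 2M for M factors; bits (2m, 2m+1) are the m-th
    factor's pair.  (0,0) is unselected; otherwise the pair is the status
    s = 2*b1 + b2 in {1,2,3} and selects level code s-1.  Statuses whose
    level code is not valid for the factor leave it unselected.
    """
    bits = np.asarray(position).astype(int)
    if bits.shape != (2 * len(factors),):
        raise ValueError(
            f"position length {bits.shape} does not match 2 x {len(factors)} factors"
        )
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("position entries must be 0/1 bits")
    selections = []
    for m, f in enumerate(factors):
        status = 2 * bits[2 * m] + bits[2 * m + 1]
        if status == 0:
            continue
        code = int(status) - 1
        if code in f.valid_codes:
            selections.append((f.name, code))
    return Barcode(tuple(selections))


def match_subject(values: Mapping[str, float], barcode: Barcode) -> str:
    """Classify one subject against a barcode: exposed/unexposed/excluded."""
    if barcode.order == 0:
        raise ValueError("cannot match against an empty barcode")
    exposed = True
    for name, code in barcode.selections:
        if name not in values:
            raise KeyError(f"subject lacks factor {name!r}")
        v = values[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return EXCLUDED
        if float(v) != float(code):
            exposed = False
    return EXPOSED if exposed else UNEXPOSED


@dataclass(frozen=True)
class BarcodeEvaluation:
    """Dual-comparison risk summary of one barcode on one cohort.

    ``table_cvn`` compares exposed vs other among cancer+control subjects,
    ``table_pvn`` among OPMD+control subjects; ``delta`` is
    OR_CvN - OR_PvN, the risk-difference criterion between the two case
    groups; ``n_excluded`` counts subjects dropped per group for missing
    values on the barcode's factors.  ``defined`` is False when a comparison
    group has no usable subjects (tables then hold NaN estimates and fitness
    is the -inf sentinel).
    """

    barcode: Barcode
    table_cvn: TwoByTwo | None
    table_pvn: TwoByTwo | None
    est_cvn: RiskEstimate
    est_pvn: RiskEstimate
    delta: float
    fitness: float
    n_excluded: Mapping[str, int]
    defined: bool = True

    @property
    def label(self) -> str:
        return format_barcode(self.barcode)


class CohortEvaluator:
    """Vectorised, cached barcode evaluation on a fixed cohort.

    Per-(factor, level) match masks and missing masks are precomputed once;
    evaluating a barcode is then a handful of boolean reductions.  Results
    are cached by barcode, so re-evaluating an identical barcode is free and
    returns the identical object (the evaluation is a pure function of the
    cohort).
    """

    def __init__(self, cohort: Cohort, alpha: float = 0.05):
        self.cohort = cohort
        self.alpha = alpha
        self._match: dict[tuple[str, int], np.ndarray] = {}
        self._miss: dict[str, np.ndarray] = {}
        for f in cohort.factors:
            vals = cohort.values(f.name)
            self._miss[f.name] = np.isnan(vals)
            for code in f.valid_codes:
                self._match[(f.name, code)] = vals == code
        self._groups = {g: cohort.group_mask(g) for g in ("control", "opmd", "cancer")}
        self._cache: dict[tuple[tuple[str, int], ...], BarcodeEvaluation] = {}
        self.n_evaluations = 0

    def evaluate(self, barcode: Barcode) -> BarcodeEvaluation:
        key = barcode.selections
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        evaluation = self._evaluate(barcode)
        self._cache[key] = evaluation
        self.n_evaluations += 1
        return evaluation

    def _evaluate(self, barcode: Barcode) -> BarcodeEvaluation:
        if barcode.order == 0:
            raise ValueError("cannot evaluate an empty barcode")
        for name, code in barcode.selections:
            if (name, code) not in self._match:
                self.cohort.factor(name)  # raises KeyError for unknown factor
                raise ValueError(f"level {code} not valid for factor {name!r}")
        excluded = np.zeros(self.cohort.n_subjects, dtype=bool)
        exposed = np.ones(self.cohort.n_subjects, dtype=bool)
        for name, code in barcode.selections:
            excluded |= self._miss[name]
            exposed &= self._match[(name, code)]
        exposed &= ~excluded
        usable = ~excluded

        counts = {}
        n_excluded = {}
        for g, mask in self._groups.items():
            counts[g] = (int(np.sum(exposed & mask)), int(np.sum(usable & mask)))
            n_excluded[g] = int(np.sum(excluded & mask))

        def _table(case_group: str) -> TwoByTwo | None:
            ce, cu = counts[case_group]
            ne, nu = counts["control"]
            if cu == 0 or nu == 0:
                return None
            return TwoByTwo(d_e=ce, h_e=ne, d_n=cu - ce, h_n=nu - ne)

        table_cvn = _table("cancer")
        table_pvn = _table("opmd")
        if table_cvn is None or table_pvn is None:
            return BarcodeEvaluation(
                barcode, table_cvn, table_pvn, _NAN_ESTIMATE, _NAN_ESTIMATE,
                float("nan"), UNDEFINED_FITNESS, n_excluded, defined=False,
            )
        est_cvn = risk_estimate(table_cvn, alpha=self.alpha)
        est_pvn = risk_estimate(table_pvn, alpha=self.alpha)
        delta = est_cvn.or_value - est_pvn.or_value
        evaluation = BarcodeEvaluation(
            barcode, table_cvn, table_pvn, est_cvn, est_pvn, delta,
            UNDEFINED_FITNESS, n_excluded, defined=True,
        )
        return BarcodeEvaluation(
            barcode, table_cvn, table_pvn, est_cvn, est_pvn, delta,
            _fitness(evaluation, alpha=self.alpha), n_excluded, defined=True,
        )


def evaluate_barcode(cohort: Cohort, barcode: Barcode, alpha: float = 0.05) -> BarcodeEvaluation:
    """Evaluate one barcode on a cohort (convenience, uncached)."""
    return CohortEvaluator(cohort, alpha=alpha).evaluate(barcode)


def evaluations_to_frame(
    evaluations: Sequence[BarcodeEvaluation], factor_order: Sequence[str] | None = None
):
    """Tabulate evaluations in the report layout (one row per barcode)."""
    import pandas as pd

    rows = []
    for ev in evaluations:
        row: dict[str, object] = {
            "model": model_label(ev.barcode, factor_order),
            "combination": format_barcode(ev.barcode, factor_order),
            "order": ev.barcode.order,
        }
        for tag, table, est in (
            ("pvn", ev.table_pvn, ev.est_pvn),
            ("cvn", ev.table_cvn, ev.est_cvn),
        ):
            row[f"cases_exposed_{tag}"] = table.d_e if table else float("nan")
            row[f"controls_exposed_{tag}"] = table.h_e if table else float("nan")
            row[f"cases_other_{tag}"] = table.d_n if table else float("nan")
            row[f"controls_other_{tag}"] = table.h_n if table else float("nan")
            row[f"or_{tag}"] = est.or_value
            row[f"ci_low_{tag}"] = est.ci_low
            row[f"ci_high_{tag}"] = est.ci_high
            row[f"p_{tag}"] = est.p_value
        row["delta"] = ev.delta
        row["fitness"] = ev.fitness
        row["n_excluded"] = sum(ev.n_excluded.values())
        rows.append(row)
    return pd.DataFrame(rows)
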