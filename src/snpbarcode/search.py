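"""Barcode search: binary particle swarm and exhaustive enumeration.

Both searches maximise the sigmoid-weighted joint odds-ratio fitness (see
:mod:`snpbarcode.objective`) over barcodes on a three-group cohort.  They
are scikit-learn style estimators: ``fit(X, y)`` takes a factor matrix
(DataFrame or array of integer codes, NaN = missing) and a group-label
vector with values ``control``/``opmd``/``cancer``, and exposes the result
through fitted attributes (``best_barcode_``, ``best_evaluation_``,
``ranking_``/``top_k_``, ``history_``).

The swarm follows the canonical binary PSO: particles carry a real velocity
per bit, updated each iteration by attraction to the particle's personal
best and the swarm's global best, clamped to [v_min, v_max]; each bit is
then redrawn as a Bernoulli with success probability sigmoid(velocity).
Positions decode to barcodes at two bits per factor.  The global best is
updated only on strict fitness improvement, so the best-fitness trace is
monotone non-decreasing and ties keep the earliest incumbent.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .barcode import Barcode, BarcodeEvaluation, CohortEvaluator, decode_particle, format_barcode
from .cohort import Cohort, FactorDefinition
from .objective import UNDEFINED_FITNESS, sigmoid

__all__ = [
    "sigmoid",
    "update_velocity",
    "update_position",
    "enumerate_barcodes",
    "count_barcodes",
    "BPSOBarcodeSearch",
    "ExhaustiveBarcodeSearch",
]


def _as_cohort(X, y, factors: Sequence[FactorDefinition] | None) -> Cohort:
    if isinstance(X, Cohort):
        return X
    return Cohort.from_arrays(X, y, factors=factors)


# -- swarm update primitives ----------------------------------------------

def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    c1: float,
    c2: float,
    v_min: float,
    v_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity update with fresh per-dimension r1, r2, then clamping.

    v <- clip(v + c1*r1*(pbest - x) + c2*r2*(gbest - x), v_min, v_max)
    """
    r1 = rng.random(velocity.shape)
    r2 = rng.random(velocity.shape)
    v = velocity + c1 * r1 * (pbest - position) + c2 * r2 * (gbest - position)
    return np.clip(v, v_min, v_max)


def update_position(velocity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Redraw each bit as 1 with probability sigmoid(velocity) (fresh r3)."""
    r3 = rng.random(velocity.shape)
    return (sigmoid(velocity) > r3).astype(np.int8)


# -- exhaustive enumeration -----------------------------------------------

def enumerate_barcodes(
    factors: Sequence[FactorDefinition],
    min_order: int = 1,
    max_order: int | None = None,
) -> Iterator[Barcode]:
    """Yield every barcode of order min_order..max_order, without duplicates.

    Factor subsets are taken in schema order and level codes in ascending
    order, so the stream is deterministic.
    """
    m = len(factors)
    if max_order is None:
        max_order = m
    if not (1 <= min_order <= max_order <= m):
        raise ValueError(f"invalid order range [{min_order}, {max_order}] for {m} factors")
    for k in range(min_order, max_order + 1):
        for subset in itertools.combinations(factors, k):
            code_choices = [sorted(f.valid_codes) for f in subset]
            for codes in itertools.product(*code_choices):
                yield Barcode(tuple((f.name, c) for f, c in zip(subset, codes)))


def count_barcodes(
    factors: Sequence[FactorDefinition],
    min_order: int = 1,
    max_order: int | None = None,
) -> int:
    """Closed-form enumeration size: sum over subsets of level-count products."""
    m = len(factors)
    if max_order is None:
        max_order = m
    sizes = [len(f.valid_codes) for f in factors]
    total = 0
    for k in range(min_order, max_order + 1):
        for subset in itertools.combinations(sizes, k):
            total += math.prod(subset)
    return total


def _rank_key(factor_order: Sequence[str], rank_by: str):
    def key(ev: BarcodeEvaluation):
        fit = ev.fitness if np.isfinite(ev.fitness) else -math.inf
        delta = ev.delta if np.isfinite(ev.delta) else -math.inf
        label = format_barcode(ev.barcode, factor_order)
        if rank_by == "delta":
            return (-delta, -fit, ev.barcode.order, label)
        return (-fit, -delta, ev.barcode.order, label)

    return key


class ExhaustiveBarcodeSearch(BaseEstimator):
    """Brute-force enumeration of all barcodes up to ``max_order``.

    Ground truth for validating the swarm, and exact top-k ranking tables on
    small factor panels (the study's own space of 7 SNPs + 7 environmental
    factors is fully enumerable at the orders it explores).

    Parameters
    ----------
    max_order : int or None
        Largest barcode order to enumerate (None = all factors).
    min_order : int
        Smallest order (default 1).
    top_k : int
        Number of ranked evaluations kept in ``ranking_``.
    rank_by : {"fitness", "delta"}
        Primary ranking key; ties break by the other key, then lower order,
        then combination label.
    alpha : float
        Significance level for the fitness indicator and CIs.
    max_evaluations : int
        Safety bound; fitting refuses (ValueError naming the computed size)
        when the enumeration would exceed it.

    Attributes
    ----------
    ranking_ : list of BarcodeEvaluation
        Top-k evaluations in rank order.
    best_evaluation_, best_barcode_ : top-ranked result.
    n_evaluations_ : number of barcodes evaluated.
    """

    def __init__(
        self,
        max_order: int | None = None,
        min_order: int = 1,
        top_k: int = 10,
        rank_by: str = "fitness",
        alpha: float = 0.05,
        max_evaluations: int = 1_000_000,
    ):
        self.max_order = max_order
        self.min_order = min_order
        self.top_k = top_k
        self.rank_by = rank_by
        self.alpha = alpha
        self.max_evaluations = max_evaluations

    def fit(self, X, y=None, factors: Sequence[FactorDefinition] | None = None):
        if self.rank_by not in ("fitness", "delta"):
            raise ValueError("rank_by must be 'fitness' or 'delta'")
        cohort = _as_cohort(X, y, factors)
        size = count_barcodes(cohort.factors, self.min_order, self.max_order)
        if size > self.max_evaluations:
            raise ValueError(
                f"enumeration of {size} barcodes exceeds the safety bound "
                f"({self.max_evaluations}); raise max_evaluations or lower max_order"
            )
        evaluator = CohortEvaluator(cohort, alpha=self.alpha)
        evaluations = [
            evaluator.evaluate(bc)
            for bc in enumerate_barcodes(cohort.factors, self.min_order, self.max_order)
        ]
        evaluations.sort(key=_rank_key(cohort.factor_names, self.rank_by))
        self.factor_names_ = list(cohort.factor_names)
        self.n_evaluations_ = len(evaluations)
        self.ranking_ = evaluations[: self.top_k]
        self.best_evaluation_ = evaluations[0] if evaluations else None
        self.best_barcode_ = self.best_evaluation_.barcode if evaluations else None
        return self


class BPSOBarcodeSearch(BaseEstimator):
    """Binary particle swarm search for the maximum-fitness barcode.

    Procedure: initialise N particles with uniform random bits and uniform
    velocities on [v_min, v_max]; then for each of ``n_iterations``
    iterations evaluate every particle's decoded barcode, update personal
    and global bests on strict improvement, and move the swarm with the
    velocity/sigmoid/Bernoulli updates.  All randomness flows from
    ``random_state``; identical seeds give identical results.

    Parameters
    ----------
    n_particles, n_iterations : int
        Swarm size and iteration budget (the only stopping rule).
    c1, c2 : float
        Acceleration coefficients toward the personal and global bests.
    v_min, v_max : float
        Velocity clamp bounds.
    max_order : int or None
        Optional cap on barcode order; decoded barcodes above the cap get
        sentinel (-inf) fitness rather than being repaired.
    alpha : float
        Significance level for the fitness indicator.
    top_k : int
        Number of distinct best barcodes kept in ``top_k_``.
    random_state : int, Generator or None
        Seed for the single generator driving initialisation and updates.

    Attributes
    ----------
    best_barcode_, best_evaluation_ : global best after the final iteration.
    history_ : ndarray of the global-best fitness after each evaluation
        phase (length n_iterations + 1, monotone non-decreasing).
    n_evaluations_ : count of fitness evaluations (cache lookups included).
    top_k_ : distinct evaluated barcodes ranked by fitness (ties: lower
        order first, then combination label).
    """

    def __init__(
        self,
        n_particles: int = 50,
        n_iterations: int = 100,
        c1: float = 2.0,
        c2: float = 2.0,
        v_min: float = -2.0,
        v_max: float = 2.0,
        max_order: int | None = None,
        alpha: float = 0.05,
        top_k: int = 10,
        random_state=None,
    ):
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.c1 = c1
        self.c2 = c2
        self.v_min = v_min
        self.v_max = v_max
        self.max_order = max_order
        self.alpha = alpha
        self.top_k = top_k
        self.random_state = random_state

    def _check_params(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")
        if not self.v_min < self.v_max:
            raise ValueError("v_min must be strictly below v_max")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration coefficients must be non-negative")

    def fit(self, X, y=None, factors: Sequence[FactorDefinition] | None = None):
        self._check_params()
        cohort = _as_cohort(X, y, factors)
        if not cohort.factors:
            raise ValueError("cohort has no factors to search over")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        evaluator = CohortEvaluator(cohort, alpha=self.alpha)
        n, d = self.n_particles, 2 * len(cohort.factors)
        positions = rng.integers(0, 2, size=(n, d)).astype(np.int8)
        velocities = rng.uniform(self.v_min, self.v_max, size=(n, d))

        # Bounded re-sampling of particles that decode to the empty barcode,
        # so the initial swarm carries at least some evaluable solutions.
        for i in range(n):
            for _ in range(20):
                if decode_particle(positions[i], cohort.factors).order > 0:
                    break
                positions[i] = rng.integers(0, 2, size=d).astype(np.int8)

        n_calls = 0

        def evaluate(position: np.ndarray) -> tuple[float, BarcodeEvaluation | None]:
            nonlocal n_calls
            n_calls += 1
            bc = decode_particle(position, cohort.factors)
            if bc.order == 0:
                return UNDEFINED_FITNESS, None
            if self.max_order is not None and bc.order > self.max_order:
                # Graded infeasibility penalty: strictly below any defined
                # fitness (which is positive), decreasing in the violation,
                # so the swarm is steered toward the feasible region instead
                # of wandering a flat sentinel plateau.
                return -float(bc.order - self.max_order), None
            ev = evaluator.evaluate(bc)
            return ev.fitness, ev

        pbest_pos = positions.copy()
        pbest_fit = np.full(n, -np.inf)
        gbest_pos = positions[0].copy()
        gbest_fit = -np.inf
        gbest_eval: BarcodeEvaluation | None = None
        history = []

        for iteration in range(self.n_iterations + 1):
            if iteration > 0:
                for i in range(n):
                    velocities[i] = update_velocity(
                        velocities[i], positions[i], pbest_pos[i], gbest_pos,
                        self.c1, self.c2, self.v_min, self.v_max, rng,
                    )
                    positions[i] = update_position(velocities[i], rng)
            for i in range(n):
                fit, ev = evaluate(positions[i])
                if fit > pbest_fit[i]:
                    pbest_fit[i] = fit
                    pbest_pos[i] = positions[i].copy()
                if fit > gbest_fit:
                    gbest_fit = fit
                    gbest_pos = positions[i].copy()
                    gbest_eval = ev
            history.append(gbest_fit)

        ranked = sorted(
            evaluator._cache.values(),
            key=lambda ev: (
                -(ev.fitness if np.isfinite(ev.fitness) else -math.inf),
                ev.barcode.order,
                format_barcode(ev.barcode, cohort.factor_names),
            ),
        )
        self.factor_names_ = list(cohort.factor_names)
        self.best_evaluation_ = gbest_eval
        self.best_barcode_ = gbest_eval.barcode if gbest_eval is not None else None
        self.best_fitness_ = float(gbest_fit)
        self.history_ = np.asarray(history)
        self.n_evaluations_ = n_calls
        self.top_k_ = ranked[: self.top_k]
        return self
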