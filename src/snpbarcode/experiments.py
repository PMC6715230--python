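"""Calibration experiments validating the swarm search against ground truth.

Two standing experiments, fully seeded:

* **Oracle equivalence** — on planted synthetic cohorts over a small (8
  factor) panel, the swarm (N=50 particles, 100 iterations, barcode order
  capped at 3) must attain the exhaustive enumeration's maximum fitness.

* **Planted recovery** — on a study-panel cohort with a planted 3-factor
  effect (cancer OR 8, OPMD OR 4 against the realised control exposure),
  independent swarm runs must return the planted barcode as the global
  best.  The cohort is first screened with the exhaustive oracle so that
  the planted barcode really is the cohort's fitness optimum — at this
  sample size a sampling-noise fluke can legitimately displace it (see
  :func:`planted_optimum_rate`, which measures exactly how often) — and
  the experiment then isolates the search's reliability.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .barcode import Barcode
from .search import BPSOBarcodeSearch, ExhaustiveBarcodeSearch
from .simulate import (
    GeneratorConfig,
    PlantedEffect,
    STUDY_GROUP_SIZES,
    generate_cohort,
    study_config,
    study_factor_panel,
)

#: The standing planted effect: three factor levels of moderate background
#: frequency (so that dropping any member dilutes the joint signal), with the
#: cancer risk double the OPMD risk as in the study's own best models.
RECOVERY_BARCODE = Barcode((("education", 2), ("betel_quid", 1), ("rs887844", 1)))
RECOVERY_TARGETS = {"cancer": 8.0, "opmd": 4.0}

#: 8-factor sub-panel for the oracle-equivalence cohorts.
ORACLE_PANEL = (
    "age", "race", "education", "alcohol", "betel_quid", "cigarette",
    "rs4411227", "rs887844",
)

SEARCH_PARAMS = dict(n_particles=50, n_iterations=100, max_order=3)


def _recovery_effect() -> PlantedEffect:
    return PlantedEffect(RECOVERY_BARCODE, RECOVERY_TARGETS)


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _oracle_config() -> GeneratorConfig:
    specs = [s for s in study_factor_panel() if s.definition.name in ORACLE_PANEL]
    return GeneratorConfig(
        group_sizes=STUDY_GROUP_SIZES,
        factor_specs=specs,
        planted=[_recovery_effect()],
    )


def oracle_equivalence(n_cohorts: int = 20, seed: int = 0) -> dict:
    """Fraction of swarm runs attaining the exhaustive-best fitness.

    One swarm run per cohort, each with its own derived seed.  Returns a
    dict with ``hits``, ``n`` and ``rate_pct``.
    """
    seeds = _derive_seeds(seed, 2 * n_cohorts)
    hits = 0
    for i in range(n_cohorts):
        cohort, _ = generate_cohort(_oracle_config(), seed=int(seeds[i]))
        oracle = ExhaustiveBarcodeSearch(max_order=3, top_k=1).fit(cohort)
        swarm = BPSOBarcodeSearch(
            **SEARCH_PARAMS, random_state=int(seeds[n_cohorts + i])
        ).fit(cohort)
        if abs(swarm.best_fitness_ - oracle.best_evaluation_.fitness) < 1e-9:
            hits += 1
    return {"hits": hits, "n": n_cohorts, "rate_pct": 100.0 * hits / n_cohorts}


def planted_recovery(
    n_runs: int = 20, seed: int = 0, max_cohort_attempts: int = 10
) -> dict:
    """Fraction of swarm runs whose global best is the planted barcode.

    A study-panel cohort is generated and screened with the exhaustive
    oracle until the planted barcode is its verified fitness optimum (the
    number of attempts is reported), then ``n_runs`` independently seeded
    swarm runs are scored.
    """
    seeds = _derive_seeds(seed, max_cohort_attempts + n_runs)
    config = study_config(planted=[_recovery_effect()])
    cohort = None
    attempts = 0
    for attempts in range(1, max_cohort_attempts + 1):
        candidate, _ = generate_cohort(config, seed=int(seeds[attempts - 1]))
        oracle = ExhaustiveBarcodeSearch(max_order=3, top_k=1).fit(candidate)
        if set(oracle.best_barcode_.selections) == set(RECOVERY_BARCODE.selections):
            cohort = candidate
            break
    if cohort is None:
        raise RuntimeError(
            f"no cohort with the planted optimum in {max_cohort_attempts} attempts"
        )
    recovered = 0
    for j in range(n_runs):
        swarm = BPSOBarcodeSearch(
            **SEARCH_PARAMS, random_state=int(seeds[max_cohort_attempts + j])
        ).fit(cohort)
        if swarm.best_barcode_ is not None and set(
            swarm.best_barcode_.selections
        ) == set(RECOVERY_BARCODE.selections):
            recovered += 1
    return {
        "recovered": recovered,
        "n": n_runs,
        "rate_pct": 100.0 * recovered / n_runs,
        "cohort_attempts": attempts,
    }


def planted_optimum_rate(n_cohorts: int = 20, seed: int = 0) -> dict:
    """How often the planted barcode is the true fitness optimum.

    Generator-level property of the planted effect at study scale: the
    complement is the rate at which sampling noise hands the optimum to
    another barcode.
    """
    seeds = _derive_seeds(seed, n_cohorts)
    config = study_config(planted=[_recovery_effect()])
    wins = 0
    for i in range(n_cohorts):
        cohort, _ = generate_cohort(config, seed=int(seeds[i]))
        oracle = ExhaustiveBarcodeSearch(max_order=3, top_k=1).fit(cohort)
        if set(oracle.best_barcode_.selections) == set(RECOVERY_BARCODE.selections):
            wins += 1
    return {"wins": wins, "n": n_cohorts, "rate_pct": 100.0 * wins / n_cohorts}
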