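"""Seeded synthetic case-control cohorts with optional planted joint effects.

The generator emulates the structure of a three-group oral-malignancy
case-control study: a control group, an OPMD group and an oral/pharyngeal
cancer group (default sizes 264/70/242), a panel of 7 environmental factors
and 7 SNPs with the study control group's marginal level frequencies, and
optional *planted* multi-factor barcodes whose joint exposure odds in each
case group are set to a target odds ratio against the realised control
exposure.  Missingness, when requested, is completely at random and applied
last.

Planting model: controls are drawn independently per factor; for a planted
barcode the realised control exposure odds o_ctrl are measured, and each
case-group subject is exposed with probability p solved from
``p/(1-p) = OR_target * o_ctrl``.  Exposed subjects receive the barcode's
levels jointly; non-exposed subjects draw the member factors from the
background conditioned on *not* matching the full barcode.  Non-member
factors are always independent background draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import Barcode
from .cohort import GROUPS, Cohort, FactorDefinition


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class FactorSpec:
    """A factor definition plus its per-group level frequencies.

    ``frequencies`` maps level code -> probability, applied to every group;
    per-group overrides can be given in ``group_frequencies``.
    """

    definition: FactorDefinition
    frequencies: Mapping[int, float]
    group_frequencies: Mapping[str, Mapping[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", dict(self.frequencies))
        object.__setattr__(
            self, "group_frequencies", {g: dict(f) for g, f in self.group_frequencies.items()}
        )
        for freqs in (self.frequencies, *self.group_frequencies.values()):
            if set(freqs) - set(self.definition.valid_codes):
                raise ConfigError(
                    f"factor {self.definition.name!r}: frequency codes outside valid codes"
                )
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"factor {self.definition.name!r}: frequencies sum to {total}, not 1"
                )
            if any(p < 0 for p in freqs.values()):
                raise ConfigError(f"factor {self.definition.name!r}: negative frequency")

    def freqs_for(self, group: str) -> dict[int, float]:
        return dict(self.group_frequencies.get(group, self.frequencies))


@dataclass(frozen=True)
class PlantedEffect:
    """A barcode planted at per-case-group target odds ratios vs control."""

    barcode: Barcode
    target_or: Mapping[str, float]  # e.g. {"cancer": 8.0, "opmd": 4.0}

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_or", dict(self.target_or))
        if set(self.target_or) - {"opmd", "cancer"}:
            raise ConfigError("target_or keys must be case groups ('opmd', 'cancer')")
        if any(v <= 0 for v in self.target_or.values()):
            raise ConfigError("target odds ratios must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    group_sizes: Mapping[str, int]
    factor_specs: Sequence[FactorSpec]
    planted: Sequence[PlantedEffect] = ()
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", dict(self.group_sizes))
        object.__setattr__(self, "factor_specs", tuple(self.factor_specs))
        object.__setattr__(self, "planted", tuple(self.planted))
        if set(self.group_sizes) != set(GROUPS):
            raise ConfigError(f"group_sizes must cover exactly {GROUPS}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must lie in [0, 1)")
        names = [s.definition.name for s in self.factor_specs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate factor names in factor_specs")
        planted_names: set[str] = set()
        for effect in self.planted:
            members = set(effect.barcode.factor_names)
            if members - set(names):
                raise ConfigError(
                    f"planted barcode references unknown factors: {sorted(members - set(names))}"
                )
            if members & planted_names:
                raise ConfigError("planted barcodes must not share factors")
            planted_names |= members

    @property
    def factors(self) -> list[FactorDefinition]:
        return [s.definition for s in self.factor_specs]


def _draw_factor(rng: np.random.Generator, freqs: Mapping[int, float], size: int) -> np.ndarray:
    codes = np.array(sorted(freqs), dtype=float)
    probs = np.array([freqs[int(c)] for c in codes])
    return rng.choice(codes, size=size, p=probs / probs.sum())


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[Cohort, dict]:
    """Generate a cohort from the config; returns (cohort, truth record).

    ``seed`` overrides ``config.seed``.  The truth record carries, per
    planted barcode, the solved exposure probabilities and the realised
    exposure counts per group (before missingness).  Identical seeds give
    byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    specs = config.factor_specs
    names = [s.definition.name for s in specs]

    frames: dict[str, pd.DataFrame] = {}
    # Controls first: their realised exposure anchors the planted odds.
    for group in ("control", "opmd", "cancer"):
        n = config.group_sizes[group]
        frames[group] = pd.DataFrame(
            {s.definition.name: _draw_factor(rng, s.freqs_for(group), n) for s in specs}
        )

    truth: dict = {"planted": [], "seed": config.seed if seed is None else seed}
    for effect in config.planted:
        members = list(effect.barcode.selections)
        ctrl = frames["control"]
        exposed_ctrl = np.ones(len(ctrl), dtype=bool)
        for fname, code in members:
            exposed_ctrl &= ctrl[fname].to_numpy() == code
        n_exp = int(exposed_ctrl.sum())
        n_ctrl = len(ctrl)
        desc = ",".join(f"{n}={c}" for n, c in effect.barcode.selections)
        if n_exp == 0 or n_exp == n_ctrl:
            raise ConfigError(
                f"planted barcode {desc}: realised control exposure "
                f"{n_exp}/{n_ctrl} gives no finite odds; use commoner levels or more controls"
            )
        odds_ctrl = n_exp / (n_ctrl - n_exp)
        record = {
            "barcode": [list(s) for s in effect.barcode.selections],
            "target_or": dict(effect.target_or),
            "control_exposed": n_exp,
            "exposure_probability": {},
            "case_exposed": {},
        }
        for group in ("opmd", "cancer"):
            target = effect.target_or.get(group)
            if target is None:
                continue
            odds_case = target * odds_ctrl
            p_case = odds_case / (1.0 + odds_case)
            if not (0.0 < p_case < 1.0):
                raise ConfigError(
                    f"planted barcode {desc}: target OR {target} for "
                    f"{group} requires exposure probability {p_case}"
                )
            frame = frames[group]
            n = len(frame)
            # Exact-count planting: expose floor(n*p) subjects plus one more
            # with probability frac(n*p), at uniformly chosen positions.  The
            # realized case exposure then sits at its expectation (mean OR on
            # target), with only the control-side anchoring left stochastic.
            n_exposed = int(np.floor(n * p_case))
            if rng.random() < n * p_case - n_exposed:
                n_exposed += 1
            exposed = np.zeros(n, dtype=bool)
            exposed[rng.choice(n, size=n_exposed, replace=False)] = True
            member_names = [f for f, _ in members]
            for i in np.flatnonzero(exposed):
                for fname, code in members:
                    frame.loc[i, fname] = float(code)
            # Non-exposed subjects must not match the full barcode: redraw
            # the member factors jointly from background until they differ.
            group_freqs = {f: next(s for s in specs if s.definition.name == f).freqs_for(group)
                           for f in member_names}
            for i in np.flatnonzero(~exposed):
                for _ in range(1000):
                    match = all(frame.loc[i, f] == code for f, code in members)
                    if not match:
                        break
                    for fname, _ in members:
                        frame.loc[i, fname] = _draw_factor(rng, group_freqs[fname], 1)[0]
                else:  # pragma: no cover - requires a near-degenerate background
                    raise ConfigError(
                        f"could not draw a non-matching background for {effect.barcode}"
                    )
            record["exposure_probability"][group] = p_case
            record["case_exposed"][group] = int(exposed.sum())
        truth["planted"].append(record)

    parts = []
    for group in GROUPS:
        frame = frames[group].copy()
        frame.insert(0, "group", group)
        frame.index = [f"{group[:3]}{i:04d}" for i in range(len(frame))]
        parts.append(frame)
    data = pd.concat(parts)

    if config.missing_rate > 0:
        mask = rng.random((len(data), len(names))) < config.missing_rate
        for j, name in enumerate(names):
            col = data[name].to_numpy(dtype=float)
            col[mask[:, j]] = np.nan
            data[name] = col

    return Cohort(config.factors, data), truth


# -- the study's default factor panel --------------------------------------

#: Control-group marginal level frequencies of the study panel: seven
#: environmental factors and seven CYP26-family SNPs.  SNPs where one
#: homozygote class was never observed are coded {1, 2}.
_STUDY_PANEL: list[tuple[str, str, dict[int, str], dict[int, float]]] = [
    ("sex", "environment", {1: "male", 2: "female"}, {1: 1.0, 2: 0.0}),
    ("age", "environment", {1: "<=50", 2: ">50"}, {1: 0.7803, 2: 0.2197}),
    ("race", "environment", {1: "Minnan", 2: "other"}, {1: 0.7917, 2: 0.2083}),
    ("education", "environment", {1: "<=6y", 2: ">6y"}, {1: 0.2235, 2: 0.7765}),
    ("alcohol", "environment", {0: "no", 1: "yes"}, {0: 0.2879, 1: 0.7121}),
    ("betel_quid", "environment", {0: "no", 1: "yes"}, {0: 0.1667, 1: 0.8333}),
    ("cigarette", "environment", {0: "no", 1: "yes"}, {0: 0.0720, 1: 0.9280}),
    ("rs4411227", "snp", {0: "C/C", 1: "C/G", 2: "G/G"}, {0: 0.0227, 1: 0.2008, 2: 0.7765}),
    ("rs887844", "snp", {1: "A/G", 2: "G/G"}, {1: 0.3750, 2: 0.6250}),
    ("rs707718", "snp", {0: "G/G", 1: "G/T", 2: "T/T"}, {0: 0.1061, 1: 0.5265, 2: 0.3674}),
    ("rs3768647", "snp", {1: "C/G", 2: "G/G"}, {1: 1.0, 2: 0.0}),
    ("rs9309462", "snp", {1: "C/T", 2: "T/T"}, {1: 0.0114, 2: 0.9886}),
    ("rs8211", "snp", {0: "C/C", 1: "C/T", 2: "T/T"}, {0: 0.7500, 1: 0.2273, 2: 0.0227}),
    ("rs12256889", "snp", {1: "A/C", 2: "C/C"}, {1: 0.9773, 2: 0.0227}),
]

#: The study's group sizes: controls / OPMD / oral-pharyngeal cancer.
STUDY_GROUP_SIZES: dict[str, int] = {"control": 264, "opmd": 70, "cancer": 242}


def study_factor_panel() -> list[FactorSpec]:
    """The 14-factor study panel with control-group frequencies everywhere."""
    return [
        FactorSpec(FactorDefinition(name, kind, levels), freqs)
        for name, kind, levels, freqs in _STUDY_PANEL
    ]


def study_config(
    planted: Sequence[PlantedEffect] = (),
    missing_rate: float = 0.0,
    seed: int | None = None,
    group_sizes: Mapping[str, int] | None = None,
) -> GeneratorConfig:
    """Generator config at study scale with the default panel."""
    return GeneratorConfig(
        group_sizes=dict(group_sizes or STUDY_GROUP_SIZES),
        factor_specs=study_factor_panel(),
        planted=planted,
        missing_rate=missing_rate,
        seed=seed,
    )


# -- reconstruction from printed contingency cells -------------------------

def cohort_from_counts(
    rows: Sequence[tuple[Barcode, Mapping[str, int], Mapping[str, int]]],
    factors: Sequence[FactorDefinition],
) -> Cohort:
    """Minimal cohort reproducing printed exposed/other cells exactly.

    Each row is ``(barcode, exposed_counts, other_counts)`` with per-group
    counts (groups absent from a mapping get 0 subjects).  Exposed subjects
    carry the barcode's levels on its member factors; "other" subjects carry
    the barcode's levels except on one member factor, flipped to a different
    valid code; all non-member factors are missing, so evaluating a row's
    barcode reproduces exactly the supplied cells.

    With several rows, a row's subjects are excluded (by missingness) from
    any other row's barcode unless the barcodes are nested, so nested
    families should be reconstructed one row at a time.
    """
    factors = list(factors)
    by_name = {f.name: f for f in factors}
    records: list[dict] = []
    groups: list[str] = []
    for barcode, exposed_counts, other_counts in rows:
        for fname in barcode.factor_names:
            if fname not in by_name:
                raise ValueError(f"barcode factor {fname!r} not in schema")
        flip_name, flip_code = None, None
        for fname, code in barcode.selections:
            alternatives = sorted(by_name[fname].valid_codes - {code})
            if alternatives:
                flip_name, flip_code = fname, alternatives[0]
                break
        if flip_name is None:
            raise ValueError(
                f"barcode {barcode} has no factor with an alternative level for 'other' subjects"
            )
        for group in GROUPS:
            for status, count in (("exposed", exposed_counts.get(group, 0)),
                                  ("other", other_counts.get(group, 0))):
                if count < 0:
                    raise ValueError("counts must be non-negative")
                base = {f.name: np.nan for f in factors}
                base.update({f: float(c) for f, c in barcode.selections})
                if status == "other":
                    base[flip_name] = float(flip_code)
                records.extend([dict(base)] * count)
                groups.extend([group] * count)
    data = pd.DataFrame(records, columns=[f.name for f in factors])
    data.insert(0, "group", groups)
    data.index = pd.Index([f"s{i:05d}" for i in range(len(data))])
    return Cohort(factors, data)
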