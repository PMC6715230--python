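"""Three-group case-control cohort: data model, I/O, and descriptive QC.

A cohort holds subjects from three groups — ``control``, ``opmd`` (oral
potentially malignant disorders) and ``cancer`` (oral/pharyngeal cancer) —
with integer-coded factor columns.  SNP genotypes are coded 0/1/2 (major
homozygote / heterozygote / minor homozygote; factors where one homozygote
class is absent use codes {1,2} only) and environmental factors use small
integer category codes (e.g. age 1 = "<=50", 2 = ">50"; habits 0 = no,
1 = yes).  Missing values are allowed and never imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import chdtrc
from scipy.stats import chi2_contingency

GROUPS: tuple[str, ...] = ("control", "opmd", "cancer")

#: Tokens read as a missing value in delimited input.
MISSING_TOKENS: tuple[str, ...] = ("NA", "", "-")


class SchemaError(ValueError):
    """The file layout does not match the declared factor schema."""


class DataError(ValueError):
    """A data value violates the schema (bad group label or factor code)."""


@dataclass(frozen=True)
class FactorDefinition:
    """A coded factor: a SNP genotype or an environmental category.

    Parameters
    ----------
    name : str
        Column name, unique within a cohort.
    kind : {"snp", "environment"}
    levels : mapping of int -> str
        Label for each valid integer code, e.g. ``{1: "A/G", 2: "G/G"}`` or
        ``{1: "<=50", 2: ">50"}``.  The key set *is* the factor's valid codes.
    """

    name: str
    kind: str
    levels: Mapping[int, str]

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "environment"):
            raise ValueError(f"factor {self.name!r}: kind must be 'snp' or 'environment'")
        if not self.levels:
            raise ValueError(f"factor {self.name!r}: at least one level is required")
        if not all(isinstance(k, (int, np.integer)) for k in self.levels):
            raise ValueError(f"factor {self.name!r}: level codes must be integers")
        object.__setattr__(self, "levels", dict(self.levels))

    @property
    def valid_codes(self) -> frozenset[int]:
        return frozenset(int(k) for k in self.levels)


class Cohort:
    """Validated cohort: an ordered factor schema plus a subject table.

    The subject table is a :class:`pandas.DataFrame` indexed by subject id
    with a ``group`` column and one float column per factor (``NaN`` marks a
    missing value).
    """

    def __init__(self, factors: Sequence[FactorDefinition], data: pd.DataFrame):
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise SchemaError("factor names must be unique")
        if "group" not in data.columns:
            raise SchemaError("cohort table must have a 'group' column")
        missing_cols = [n for n in names if n not in data.columns]
        if missing_cols:
            raise SchemaError(f"cohort table lacks factor columns: {missing_cols}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate subject ids: {dupes}")
        bad_groups = sorted(set(data["group"]) - set(GROUPS))
        if bad_groups:
            raise DataError(f"unknown group labels: {bad_groups} (expected {GROUPS})")

        table = data[["group", *names]].copy()
        for f in factors:
            col = pd.to_numeric(table[f.name], errors="coerce").astype(float)
            observed = set(col.dropna().unique())
            invalid = observed - {float(c) for c in f.valid_codes}
            if invalid:
                rows = table.index[col.isin(invalid)].tolist()
                raise DataError(
                    f"factor {f.name!r}: codes {sorted(invalid)} outside valid codes "
                    f"{sorted(f.valid_codes)} (subjects {rows})"
                )
            table[f.name] = col
        self.factors: tuple[FactorDefinition, ...] = tuple(factors)
        self.data: pd.DataFrame = table

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def factor(self, name: str) -> FactorDefinition:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def values(self, name: str) -> np.ndarray:
        """Float array of codes for one factor, NaN for missing."""
        return self.data[name].to_numpy(dtype=float)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.data["group"] == group).to_numpy()

    def to_Xy(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Factor matrix and group-label vector, for estimator ``fit(X, y)``."""
        return self.data[self.factor_names].copy(), self.data["group"].to_numpy()

    @classmethod
    def from_arrays(
        cls,
        X,
        y,
        factors: Sequence[FactorDefinition] | None = None,
        ids: Sequence[str] | None = None,
    ) -> "Cohort":
        """Build a cohort from a factor matrix and group labels.

        ``X`` may be a DataFrame (column names become factor names) or a 2-D
        array.  When ``factors`` is omitted, definitions are inferred from
        the observed codes (kind 'snp' for names starting with 'rs').
        """
        if isinstance(X, pd.DataFrame):
            frame = X.copy()
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise SchemaError("X must be 2-dimensional")
            cols = (
                [f.name for f in factors]
                if factors is not None
                else [f"factor_{j}" for j in range(arr.shape[1])]
            )
            frame = pd.DataFrame(arr, columns=cols)
        y = np.asarray(y)
        if len(y) != len(frame):
            raise SchemaError("X and y have different lengths")
        if factors is None:
            factors = infer_factors(frame)
        frame.index = (
            pd.Index(ids) if ids is not None else pd.Index([f"s{i:05d}" for i in range(len(frame))])
        )
        frame.insert(0, "group", y)
        return cls(factors, frame)


def infer_factors(X: pd.DataFrame) -> list[FactorDefinition]:
    """Infer factor definitions from observed codes in a factor matrix."""
    factors = []
    for name in X.columns:
        col = pd.to_numeric(X[name], errors="coerce").dropna()
        codes = sorted(int(v) for v in col.unique())
        if not codes:
            raise DataError(f"factor {name!r}: no observed codes to infer levels from")
        kind = "snp" if str(name).startswith("rs") else "environment"
        factors.append(FactorDefinition(name, kind, {c: str(c) for c in codes}))
    return factors


# -- I/O -------------------------------------------------------------------

def read_cohort(path: str | Path, schema: Sequence[FactorDefinition]) -> Cohort:
    """Read a delimited cohort file (comma or tab, auto-detected).

    The header must contain ``subject_id``, ``group`` and one column per
    schema factor; the tokens ``NA``, empty and ``-`` are read as missing.
    Out-of-domain codes and unknown group labels raise :class:`DataError`
    naming the offending subjects.
    """
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(
        io.StringIO(text),
        sep=sep,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype={"subject_id": str, "group": str},
    )
    required = {"subject_id", "group", *(f.name for f in schema)}
    missing = sorted(required - set(frame.columns))
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    frame = frame.set_index("subject_id")
    return Cohort(schema, frame)


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort back to delimited text (round-trips with read_cohort)."""
    out = cohort.data.copy()
    for name in cohort.factor_names:
        out[name] = out[name].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "subject_id"
    out.to_csv(path, sep=sep)


# -- descriptive statistics ------------------------------------------------

def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-factor level x group distribution table.

    One row per factor level with per-group counts and percentages (of the
    group's non-missing subjects) and a Pearson chi-square p-value (no
    continuity correction) for the level x group contingency table, repeated
    on each of the factor's rows.  A factor with a single observed level gets
    an undefined (NaN) p-value.
    """
    rows = []
    group_masks = {g: cohort.group_mask(g) for g in GROUPS}
    for f in cohort.factors:
        vals = cohort.values(f.name)
        codes = sorted(f.valid_codes)
        counts = {
            g: np.array([np.sum((vals == c) & m) for c in codes])
            for g, m in group_masks.items()
        }
        observed = np.column_stack([counts[g] for g in GROUPS])
        nonzero_rows = observed[observed.sum(axis=1) > 0]
        nonzero = nonzero_rows[:, nonzero_rows.sum(axis=0) > 0]
        if nonzero.shape[0] > 1 and nonzero.shape[1] > 1:
            p_value = float(chi2_contingency(nonzero, correction=False).pvalue)
        else:
            p_value = float("nan")
        for i, c in enumerate(codes):
            row: dict[str, object] = {
                "factor": f.name,
                "kind": f.kind,
                "level": c,
                "label": f.levels[c],
                "p_value": p_value,
            }
            for g in GROUPS:
                n_group = counts[g].sum()
                row[f"n_{g}"] = int(counts[g][i])
                row[f"pct_{g}"] = 100.0 * counts[g][i] / n_group if n_group else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def hwe_test(n_hom_a: int, n_het: int, n_hom_b: int) -> tuple[float, float]:
    """Hardy-Weinberg goodness-of-fit chi-square (1 df) from genotype counts.

    Allele frequencies are estimated from the counts; expected genotype
    counts are n*(p^2, 2pq, q^2).  Returns ``(statistic, p_value)``.  A
    monomorphic sample (one allele fixed) fits exactly and returns (0, 1).
    The test is symmetric in the two homozygote counts.
    """
    counts = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotyped subjects")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p**2, 2 * p * q, q * q])
    mask = expected > 0
    stat = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return stat, float(chdtrc(1, stat))


def hwe_by_group(cohort: Cohort) -> pd.DataFrame:
    """HWE test per SNP per group.

    SNPs whose coding lacks one homozygote class (only two valid codes)
    cannot be tested and are reported not-applicable (NaN statistic/p).
    """
    rows = []
    for f in cohort.factors:
        if f.kind != "snp":
            continue
        testable = f.valid_codes == frozenset({0, 1, 2})
        vals = cohort.values(f.name)
        for g in GROUPS:
            m = cohort.group_mask(g)
            if testable:
                counts = [int(np.sum((vals == c) & m)) for c in (0, 1, 2)]
                if sum(counts) > 0:
                    stat, p = hwe_test(*counts)
                else:
                    stat, p = float("nan"), float("nan")
            else:
                stat, p = float("nan"), float("nan")
            rows.append(
                {"snp": f.name, "group": g, "chi2": stat, "p_value": p, "applicable": testable}
            )
    return pd.DataFrame(rows)
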