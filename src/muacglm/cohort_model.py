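"""Cohort data model for MUAC regression analyses.

Holds the child-level measurement table (six covariates plus the MUAC
response), builds design matrices with pairwise interaction columns, and
computes the standard descriptive and correlation summaries used to
characterize an anthropometric cohort.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

#: Covariate column names, in model-table order.
COVARIATES: tuple[str, ...] = (
    "age",
    "weight",
    "height",
    "hemoglobin",
    "protein",
    "albumen",
)

#: Response column name (mid upper arm circumference, cm).
RESPONSE = "muac"

#: All columns a cohort table must carry.
COLUMNS: tuple[str, ...] = COVARIATES + (RESPONSE,)

#: Row order of the descriptive-statistics summary.
DESCRIBE_ORDER: tuple[str, ...] = (
    "age",
    "height",
    "weight",
    "hemoglobin",
    "protein",
    "albumen",
    "muac",
)

#: Variable order of the printed correlation table.
CORRELATION_ORDER: tuple[str, ...] = (
    "age",
    "weight",
    "muac",
    "hemoglobin",
    "protein",
    "albumen",
    "height",
)

INTERCEPT_LABEL = "(Intercept)"


class CohortError(ValueError):
    """Raised for invalid cohort tables or malformed model terms."""


@dataclass(frozen=True)
class TermList:
    """Ordered model terms with an implicit leading intercept.

    Each term is either a covariate name (``"weight"``) or an ordered
    product of two covariate names (``"weight:height"``).  The intercept is
    implicit and always first; ``TermList(())`` is the intercept-only model.
    """

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.terms:
            parts = t.split(":")
            if len(parts) > 2 or any(not p for p in parts):
                raise CohortError(f"malformed term {t!r}")
            if t in seen:
                raise CohortError(f"duplicate term {t!r}")
            seen.add(t)

    @property
    def labels(self) -> tuple[str, ...]:
        """Column labels including the leading intercept."""
        return (INTERCEPT_LABEL,) + self.terms

    @property
    def p(self) -> int:
        """Number of coefficients (intercept included)."""
        return 1 + len(self.terms)

    def covariates_used(self) -> tuple[str, ...]:
        out: list[str] = []
        for t in self.terms:
            for part in t.split(":"):
                if part not in out:
                    out.append(part)
        return tuple(out)

    def without(self, term: str) -> "TermList":
        if term not in self.terms:
            raise CohortError(f"term {term!r} not present")
        return TermList(tuple(t for t in self.terms if t != term))

    @classmethod
    def parse(cls, spec: str) -> "TermList":
        """Parse a comma-separated term spec.

        ``"default10"`` is shorthand for the ten-coefficient default model;
        ``"intercept"`` (or an empty string) gives the intercept-only model.
        """
        spec = spec.strip()
        if spec == "default10":
            return DEFAULT_TERMS
        if spec in ("intercept", ""):
            return INTERCEPT_ONLY
        return cls(tuple(s.strip() for s in spec.split(",") if s.strip()))


#: Default ten-coefficient term list: six main effects plus the three
#: anthropometric interactions, in reporting order.
DEFAULT_TERMS = TermList(
    (
        "age",
        "weight",
        "height",
        "hemoglobin",
        "protein",
        "albumen",
        "weight:height",
        "age:weight",
        "age:height",
    )
)

INTERCEPT_ONLY = TermList(())


class CohortTable:
    """Validated table of child measurements.

    Parameters
    ----------
    data:
        Frame containing the columns :data:`COLUMNS`.  Rows with any missing
        cell are dropped (with a logged count).  All retained values must be
        strictly positive and finite.
    muac_unit:
        ``"cm"`` (default, stored as-is) or ``"mm"`` (converted to cm on
        ingestion).
    extra:
        Names of additional covariate columns to retain and validate
        (e.g. candidate predictors for a screening exercise).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        muac_unit: str = "cm",
        extra: tuple[str, ...] = (),
    ) -> None:
        columns = COLUMNS + tuple(c for c in extra if c not in COLUMNS)
        missing = [c for c in columns if c not in data.columns]
        if missing:
            raise CohortError(f"missing columns: {missing}")
        frame = data.loc[:, list(columns)].astype(float)
        n_before = len(frame)
        frame = frame.dropna()
        n_dropped = n_before - len(frame)
        if n_dropped:
            logger.info("dropped %d rows with missing cells", n_dropped)
        frame = frame.reset_index(drop=True)
        if muac_unit == "mm":
            frame[RESPONSE] = frame[RESPONSE] / 10.0
        elif muac_unit != "cm":
            raise CohortError(f"unknown muac_unit {muac_unit!r}")
        values = frame.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise CohortError("non-finite values in cohort table")
        if values.size and not np.all(values > 0):
            bad = [c for c in columns if (frame[c] <= 0).any()]
            raise CohortError(f"non-positive values in columns: {bad}")
        self._frame = frame
        self._columns = columns
        self.n_dropped = n_dropped

    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The validated data frame (a copy)."""
        return self._frame.copy()

    @property
    def y(self) -> np.ndarray:
        """The MUAC response vector (cm)."""
        return self._frame[RESPONSE].to_numpy()

    def column(self, name: str) -> np.ndarray:
        if name not in self._columns:
            raise CohortError(f"unknown column {name!r}")
        return self._frame[name].to_numpy()

    @classmethod
    def empty(cls) -> "CohortTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in COLUMNS}))

    @classmethod
    def from_csv(cls, path, muac_unit: str = "cm") -> "CohortTable":
        """Read a cohort CSV (UTF-8, '.' decimal, exact column names)."""
        with open(path, "r", encoding="utf-8", newline="") as fh:
            header = next(csv.reader(fh))
        if len(header) != len(set(header)):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise CohortError(f"duplicate CSV headers: {dupes}")
        frame = pd.read_csv(path, encoding="utf-8")
        return cls(frame, muac_unit=muac_unit)

    def to_csv(self, path) -> None:
        """Write the table at full (round-tripping) float precision."""
        self._frame.to_csv(path, index=False)

    def permuted(self, order: np.ndarray) -> "CohortTable":
        """Return a row-permuted copy (utility for invariance checks)."""
        extra = tuple(c for c in self._columns if c not in COLUMNS)
        return CohortTable(self._frame.iloc[np.asarray(order)], extra=extra)

    def with_column(self, name: str, values: np.ndarray) -> "CohortTable":
        """Return a copy with an extra validated covariate column."""
        frame = self.frame
        frame[name] = np.asarray(values, dtype=float)
        extra = tuple(c for c in self._columns if c not in COLUMNS) + (name,)
        return CohortTable(frame, extra=extra)


@dataclass(frozen=True)
class DesignMatrix:
    """An n-by-p model matrix with labelled columns; first column is 1."""

    values: np.ndarray
    column_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def design_from_frame(frame: pd.DataFrame, terms: TermList) -> DesignMatrix:
    """Build a design matrix from a covariate frame (intercept first).

    Interaction columns are raw elementwise products of their parent
    columns, without centering.
    """
    n = len(frame)
    if n == 0:
        raise CohortError("cannot build a design matrix from an empty table")
    cols = [np.ones(n)]
    for t in terms.terms:
        parts = t.split(":")
        for part in parts:
            if part not in frame.columns:
                raise CohortError(f"unknown covariate {part!r} in term {t!r}")
        col = frame[parts[0]].to_numpy(dtype=float)
        if len(parts) == 2:
            col = col * frame[parts[1]].to_numpy(dtype=float)
        cols.append(col)
    return DesignMatrix(np.column_stack(cols), terms.labels)


def build_design(table: CohortTable, terms: TermList) -> DesignMatrix:
    """Design matrix for a cohort table (see :func:`design_from_frame`)."""
    return design_from_frame(table.frame, terms)


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics for one variable."""

    variable: str
    minimum: float
    maximum: float
    mean: float
    median: float
    sd: float
    n: int


def describe(table: CohortTable) -> list[SummaryRow]:
    """Per-variable descriptive statistics in fixed reporting order.

    The standard deviation uses the n-1 denominator; for a single
    observation it is reported as 0.
    """
    if table.n == 0:
        raise CohortError("cannot describe an empty table")
    rows = []
    for name in DESCRIBE_ORDER:
        v = table.column(name)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(
            SummaryRow(
                variable=name,
                minimum=float(np.min(v)),
                maximum=float(np.max(v)),
                mean=float(np.mean(v)),
                median=float(np.median(v)),
                sd=sd,
                n=len(v),
            )
        )
    return rows


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations with two-sided p-values and significance flags.

    ``p`` is NaN on the diagonal; flags are ``"**"`` for p < 0.01, ``"*"``
    for p < 0.05, ``""`` otherwise.
    """

    labels: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    flags: np.ndarray

    def pair(self, a: str, b: str) -> float:
        return float(self.r[self.labels.index(a), self.labels.index(b)])


def correlations(
    table: CohortTable, order: tuple[str, ...] = CORRELATION_ORDER
) -> CorrelationMatrix:
    """Pairwise Pearson correlation matrix over the cohort variables.

    p-values use the t transform ``t = r * sqrt((n-2)/(1-r^2))`` with n-2
    degrees of freedom, two-sided.
    """
    n = table.n
    if n < 3:
        raise CohortError("correlations require n >= 3")
    data = np.column_stack([table.column(name) for name in order])
    sds = np.std(data, axis=0)
    for j, name in enumerate(order):
        if sds[j] == 0:
            raise CohortError(f"constant column {name!r} has undefined correlation")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    k = len(order)
    p = np.full((k, k), np.nan)
    flags = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            rij = r[i, j]
            if abs(rij) == 1.0:
                p[i, j] = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
                p[i, j] = 2.0 * _sps.t.sf(abs(t), df=n - 2)
            if p[i, j] < 0.01:
                flags[i, j] = "**"
            elif p[i, j] < 0.05:
                flags[i, j] = "*"
    return CorrelationMatrix(tuple(order), r, p, flags)
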