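"""Wald coefficient tables, the backward-elimination screen, and
criterion-based model comparison.

Wald statistics are estimate/se referred to the standard normal (the
large-sample Z approximation); a Student-t option with n - p degrees of
freedom is available behind the ``dist`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .cohort_model import CohortTable, TermList
from .joint_glm import FitCriteria, JointFitResult

#: Significance-star thresholds, strongest first.
STAR_RULE: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def _stars(p: float) -> str:
    for threshold, mark in STAR_RULE:
        if p < threshold:
            return mark
    return ""


def wald_table(
    beta: np.ndarray,
    se: np.ndarray,
    labels: Sequence[str],
    dist: str = "z",
    df: int | None = None,
) -> pd.DataFrame:
    """Coefficient table with Wald t = estimate/se, two-sided p and stars.

    ``dist="z"`` uses the standard normal; ``dist="t"`` uses Student-t with
    ``df`` degrees of freedom.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (len(beta) == len(se) == len(labels)):
        raise ValueError("beta, se and labels must have equal lengths")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("standard errors must be finite and strictly positive")
    t = beta / se
    if dist == "z":
        p = 2.0 * _sps.norm.sf(np.abs(t))
    elif dist == "t":
        if df is None or df <= 0:
            raise ValueError("dist='t' requires positive df")
        p = 2.0 * _sps.t.sf(np.abs(t), df=df)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]
    return pd.DataFrame(
        {
            "term": list(labels),
            "estimate": beta,
            "se": se,
            "t": t,
            "p": p,
            "stars": [_stars(v) for v in p],
        }
    )


def mean_coefficient_table(fit: JointFitResult, dist: str = "z") -> pd.DataFrame:
    """Wald table for the mean submodel of a joint fit."""
    m = fit.mean_fit
    df = fit.n - m.X.p
    return wald_table(m.beta, m.se, m.X.column_labels, dist=dist, df=df)


def dispersion_coefficient_table(fit: JointFitResult, dist: str = "z") -> pd.DataFrame:
    """Wald table for the dispersion submodel of a joint fit."""
    d = fit.disp_fit
    df = fit.n - d.G.p
    return wald_table(d.gamma_coef, d.se, d.G.column_labels, dist=dist, df=df)


class EliminationError(RuntimeError):
    """A refit failed during backward elimination; carries the surviving terms."""

    def __init__(self, message: str, surviving: TermList):
        super().__init__(message)
        self.surviving = surviving


RefitFunc = Callable[[CohortTable, TermList], pd.DataFrame]


def backward_eliminate(
    table: CohortTable,
    candidates: TermList,
    threshold: float = 0.2,
    refit: RefitFunc | None = None,
) -> TermList:
    """Exploratory backward elimination at a retention p-value threshold.

    Repeatedly refits and drops the single term with the largest p-value at
    or above ``threshold`` until every remaining term falls below it.  The
    intercept is never dropped, and a main effect is never dropped while
    one of its interactions survives.  Ties on p are broken by
    lexicographically smallest label, so the result does not depend on the
    candidate ordering.

    ``refit(table, terms)`` must return a frame with ``term`` and ``p``
    columns (a Wald table); the default fits a constant-dispersion Gaussian
    GLM.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if refit is None:
        refit = glm_screen_refit()
    terms = TermList(tuple(sorted(candidates.terms, key=candidates.terms.index)))
    while True:
        try:
            ct = refit(table, terms)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise EliminationError(f"refit failed: {exc}", terms) from exc
        pvals = dict(zip(ct["term"], ct["p"]))
        protected = set()
        for t in terms.terms:
            if ":" in t:
                protected.update(t.split(":"))
        eligible = [
            t
            for t in terms.terms
            if t not in protected and pvals.get(t, 0.0) >= threshold
        ]
        if not eligible:
            return terms
        worst_p = max(pvals[t] for t in eligible)
        worst = min(t for t in eligible if pvals[t] == worst_p)
        terms = terms.without(worst)


def glm_screen_refit(method: str = "ml") -> RefitFunc:
    """Refit procedure for the screen: constant-dispersion Gaussian GLM."""
    from .cohort_model import INTERCEPT_ONLY
    from .joint_glm import fit_joint

    def _refit(table: CohortTable, terms: TermList) -> pd.DataFrame:
        fit = fit_joint(table, terms, INTERCEPT_ONLY, method=method)
        return mean_coefficient_table(fit)

    return _refit


@dataclass(frozen=True)
class CriterionRow:
    """One criterion across the compared models; ``best`` is None on a tie."""

    criterion: str
    values: tuple[float, ...]
    best: int | None


@dataclass(frozen=True)
class ModelComparison:
    """Per-criterion comparison; overall winner decided by lowest AIC."""

    names: tuple[str, ...]
    rows: tuple[CriterionRow, ...]
    winner: int | None

    def row(self, criterion: str) -> CriterionRow:
        for r in self.rows:
            if r.criterion == criterion:
                return r
        raise KeyError(criterion)


_CRITERIA_FIELDS = (
    ("minus2h", "-2ML (-2 h)"),
    ("minus2pbeta", "-2RL (-2 p_beta(h))"),
    ("caic", "cAIC"),
    ("aic", "AIC"),
    ("bic", "BIC"),
)


def _argmin_or_tie(values: tuple[float, ...]) -> int | None:
    best = min(values)
    idx = [i for i, v in enumerate(values) if v <= best + 1e-12 * max(1.0, abs(best))]
    return idx[0] if len(idx) == 1 else None


def compare_models(
    fits: Sequence[JointFitResult | FitCriteria],
    names: Sequence[str] | None = None,
) -> ModelComparison:
    """Compare fitted models criterion by criterion.

    Accepts joint-fit results (or bare criteria) computed on the same data;
    fits on different sample sizes are rejected.  When criteria disagree,
    the overall winner is the model with the lowest AIC; exact ties are
    reported with no winner.
    """
    if len(fits) < 2:
        raise ValueError("model comparison requires at least two fits")
    crits = [f.criteria if isinstance(f, JointFitResult) else f for f in fits]
    ns = {c.n for c in crits}
    if len(ns) != 1:
        raise ValueError(f"fits are on different sample sizes: {sorted(ns)}")
    if names is None:
        names = tuple(f"model_{i}" for i in range(len(crits)))
    rows = []
    for attr, label in _CRITERIA_FIELDS:
        values = tuple(float(getattr(c, attr)) for c in crits)
        rows.append(CriterionRow(label, values, _argmin_or_tie(values)))
    aic_values = tuple(float(c.aic) for c in crits)
    return ModelComparison(tuple(names), tuple(rows), _argmin_or_tie(aic_values))
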