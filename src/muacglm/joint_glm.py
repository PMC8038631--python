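"""Interlinked mean-dispersion fitting and likelihood-based criteria.

The joint Gaussian GLM couples a Gaussian mean submodel (identity link)
with a gamma dispersion submodel (log link) whose response is the vector of
squared residuals.  Fitting alternates between the two: the mean model is
weighted by reciprocal fitted dispersions, and the dispersion model is
refitted to the resulting deviance components, until the h-likelihood and
the mean coefficients both stabilize.

Under ML weighting the alternation fixed point is a stationary point of the
extended quasi-likelihood, here equal to -2 times the Gaussian
log-likelihood with per-observation variances phi_i:

    -2 h = sum_i [ (y_i - mu_i)^2 / phi_i + log(2 pi phi_i) ].

REML weighting replaces the dispersion response by d_i / (1 - q_i) with
prior weights (1 - q_i)/2, where q_i are mean-model leverages, which
removes the O(p/n) downward bias of ML dispersion estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort_model import (
    CohortTable,
    DesignMatrix,
    TermList,
    build_design,
)
from .glm_engine import (
    DispersionModelFit,
    MeanModelFit,
    deviance_components,
    fit_gamma_log,
    fit_gaussian,
)

logger = logging.getLogger(__name__)

JOINT_TOL = 1e-8
JOINT_MAX_ITER = 100
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitCriteria:
    """Likelihood values and information criteria for one fitted model.

    The conditional AIC penalizes only the mean-model coefficient count;
    AIC and BIC penalize mean plus dispersion coefficients.
    """

    minus2h: float
    minus2pbeta: float
    caic: float
    aic: float
    bic: float
    p_mean: int
    q_disp: int
    n: int


@dataclass(frozen=True)
class JointFitResult:
    """Converged pair of interlinked submodels with criteria and trace."""

    mean_fit: MeanModelFit
    disp_fit: DispersionModelFit
    criteria: FitCriteria
    n_iter: int
    converged: bool
    trace: tuple[float, ...]
    method: str

    @property
    def n(self) -> int:
        return self.mean_fit.X.n


def minus2h(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> float:
    """-2 times the Gaussian h-log-likelihood with heterogeneous variances."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (y.shape == mu.shape == phi.shape):
        raise ValueError("y, mu and phi must have equal lengths")
    if np.any(phi <= 0):
        raise ValueError("dispersions must be strictly positive")
    return float(np.sum((y - mu) ** 2 / phi + np.log(phi) + _LOG_2PI))


def profile_adjustment(X: DesignMatrix, phi: np.ndarray) -> float:
    """log det( X' W X / (2 pi) ) with W = diag(1/phi).

    This is the determinant correction that profiles the mean coefficients
    out of the h-likelihood.  Raises on a singular adjustment matrix.
    """
    phi = np.asarray(phi, dtype=float)
    xtwx = X.values.T @ (X.values / phi[:, None])
    sign, logdet = np.linalg.slogdet(xtwx / (2.0 * np.pi))
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            "adjustment matrix X'WX is singular; the mean design is rank deficient"
        )
    return float(logdet)


def minus2pbeta(fit: "JointFitResult") -> float:
    """-2 times the adjusted profile likelihood p_beta(h) of a joint fit."""
    phi = fit.disp_fit.phi
    m2h = float(np.sum(fit.mean_fit.d / phi + np.log(phi) + _LOG_2PI))
    return m2h + profile_adjustment(fit.mean_fit.X, phi)


def criteria_from_loglik(
    minus2h_value: float,
    p_mean: int,
    q_disp: int,
    n: int,
    minus2pbeta_value: float = float("nan"),
) -> FitCriteria:
    """Assemble :class:`FitCriteria` from likelihood values and counts.

    Identities: cAIC = -2h + 2 p_mean; AIC = -2h + 2 (p_mean + q_disp);
    BIC = -2h + (p_mean + q_disp) log n.
    """
    k = p_mean + q_disp
    return FitCriteria(
        minus2h=minus2h_value,
        minus2pbeta=minus2pbeta_value,
        caic=minus2h_value + 2.0 * p_mean,
        aic=minus2h_value + 2.0 * k,
        bic=minus2h_value + k * float(np.log(n)),
        p_mean=p_mean,
        q_disp=q_disp,
        n=n,
    )


def compute_criteria(fit: "JointFitResult") -> FitCriteria:
    """Recompute the criteria of a joint fit from its submodels."""
    y_resid_sq = fit.mean_fit.d
    phi = fit.disp_fit.phi
    m2h = float(np.sum(y_resid_sq / phi + np.log(phi) + _LOG_2PI))
    m2p = m2h + profile_adjustment(fit.mean_fit.X, phi)
    return criteria_from_loglik(
        m2h, fit.mean_fit.X.p, fit.disp_fit.G.p, fit.n, minus2pbeta_value=m2p
    )


def fit_joint(
    table: CohortTable,
    mean_terms: TermList,
    disp_terms: TermList,
    method: str = "reml",
    tol: float = JOINT_TOL,
    max_iter: int = JOINT_MAX_ITER,
) -> JointFitResult:
    """Fit the interlinked mean-dispersion model by alternation.

    Algorithm: initialize a constant dispersion from the homoscedastic OLS
    residual variance; then repeat (1) weighted Gaussian mean fit with
    prior weights 1/phi_i, (2) deviance components d_i = (y_i - mu_i)^2,
    (3) gamma-log dispersion fit -- under REML to d_i/(1-q_i) with prior
    weights (1-q_i)/2, under ML to d_i with prior weights 1/2 -- and
    (4) phi_i from its fitted values, until the change in -2h and in every
    mean coefficient falls below ``tol``.

    Non-convergence yields a result with ``converged=False`` and a logged
    warning, not an exception.
    """
    method = method.lower()
    if method not in ("ml", "reml"):
        raise ValueError(f"method must be 'ml' or 'reml', got {method!r}")
    y = table.y
    X = build_design(table, mean_terms)
    G = build_design(table, disp_terms)
    n = table.n
    if n <= X.p + G.p:
        raise ValueError(
            f"need n > p_mean + q_disp, got n={n}, p={X.p}, q={G.p}"
        )

    ols = fit_gaussian(X, y)
    phi = np.full(n, float(np.sum(ols.d)) / (n - X.p))

    trace: list[float] = []
    beta_old: np.ndarray | None = None
    m2h_old = np.inf
    converged = False
    n_iter = 0
    disp_fit: DispersionModelFit | None = None
    for n_iter in range(1, max_iter + 1):
        mean_fit = fit_gaussian(X, y, 1.0 / phi)
        d = deviance_components(y, mean_fit.mu)
        if method == "reml":
            q = np.clip(mean_fit.leverage, 0.0, 1.0 - 1e-10)
            resp = d / (1.0 - q)
            wd = (1.0 - q) / 2.0
        else:
            resp = d
            wd = np.full(n, 0.5)
        disp_fit = fit_gamma_log(resp, G, wd)
        phi = disp_fit.phi
        m2h_val = minus2h(y, mean_fit.mu, phi)
        trace.append(m2h_val)
        if beta_old is not None:
            if (
                abs(m2h_val - m2h_old) < tol
                and float(np.max(np.abs(mean_fit.beta - beta_old))) < tol
            ):
                converged = True
                break
        beta_old = mean_fit.beta
        m2h_old = m2h_val

    # final mean refit so that mean_fit.prior_weight == 1/phi at exit
    mean_fit = fit_gaussian(X, y, 1.0 / phi)
    m2h_val = minus2h(y, mean_fit.mu, phi)
    trace.append(m2h_val)
    m2p = m2h_val + profile_adjustment(X, phi)
    criteria = criteria_from_loglik(
        m2h_val, X.p, G.p, n, minus2pbeta_value=m2p
    )
    if not converged:
        logger.warning(
            "joint fit did not converge in %d iterations (|d -2h| = %.3g)",
            max_iter,
            abs(trace[-1] - trace[-2]) if len(trace) > 1 else float("nan"),
        )
    assert disp_fit is not None
    return JointFitResult(
        mean_fit=mean_fit,
        disp_fit=disp_fit,
        criteria=criteria,
        n_iter=n_iter,
        converged=converged,
        trace=tuple(trace),
        method=method,
    )
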