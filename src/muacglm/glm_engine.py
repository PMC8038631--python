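"""Single-model GLM fitters.

Two building blocks: a weighted-least-squares Gaussian fitter with identity
link (the mean submodel) and a quasi-likelihood IWLS fitter for a gamma
family with log link (the dispersion submodel, whose response is the vector
of squared residuals).  Both are thin, explicit linear-algebra routines so
that the interlinked mean-dispersion algorithm can control prior weights
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as _sla

from .cohort_model import DesignMatrix

GAMMA_TOL = 1e-10
GAMMA_MAX_ITER = 300
#: Relative floor applied to zero dispersion responses, as a fraction of the
#: response mean.
ZERO_FLOOR_REL = 1e-10


class RankDeficientError(ValueError):
    """A design matrix is not of full column rank."""


class ConvergenceError(RuntimeError):
    """IWLS failed to converge; carries the per-iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class MeanModelFit:
    """Fitted Gaussian mean submodel (identity link).

    ``d`` holds the Gaussian deviance components (y - mu)^2 in cm^2;
    ``leverage`` is the diagonal of the weighted hat matrix.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    se: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    residuals: np.ndarray
    d: np.ndarray
    leverage: np.ndarray
    prior_weight: np.ndarray
    X: DesignMatrix


@dataclass(frozen=True)
class DispersionModelFit:
    """Fitted gamma dispersion submodel (log link).

    ``phi = exp(xi)`` are the fitted per-observation dispersions (cm^2).
    The coefficient covariance is the inverse weighted cross-product from
    the final IWLS step; the quasi-dispersion factor implied by
    var(d_i) = 2 phi_i^2 is carried entirely by the prior weights, so no
    additional scale is applied here.
    """

    gamma_coef: np.ndarray
    cov_gamma: np.ndarray
    se: np.ndarray
    xi: np.ndarray
    phi: np.ndarray
    G: DesignMatrix
    prior_weight: np.ndarray
    n_iter: int


def _check_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("prior weights must be finite and strictly positive")
    return w


def _wls(values: np.ndarray, labels: tuple[str, ...], y: np.ndarray, w: np.ndarray):
    """Weighted least squares via pivoted QR.

    Returns (beta, cov, leverage) where cov = (X' W X)^{-1} with no extra
    scale factor, and leverage is the diagonal of the weighted hat matrix.
    Raises :class:`RankDeficientError` naming a dependent column.
    """
    n, p = values.shape
    if n < p:
        raise ValueError(f"need n >= p, got n={n}, p={p}")
    sw = np.sqrt(w)
    A = values * sw[:, None]
    b = y * sw
    Q, R, piv = _sla.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        raise RankDeficientError(
            f"design column {labels[piv[rank]]!r} is linearly dependent on "
            "earlier columns"
        )
    beta_piv = _sla.solve_triangular(R, Q.T @ b)
    beta = np.empty(p)
    beta[piv] = beta_piv
    r_inv = _sla.solve_triangular(R, np.eye(p))
    cov_piv = r_inv @ r_inv.T
    cov = np.empty((p, p))
    cov[np.ix_(piv, piv)] = cov_piv
    leverage = np.einsum("ij,ij->i", Q, Q)
    return beta, cov, leverage


def fit_gaussian(
    X: DesignMatrix, y: np.ndarray, w: np.ndarray | None = None
) -> MeanModelFit:
    """Fit a Gaussian GLM with identity link by weighted least squares.

    With an identity link the IWLS iteration converges in a single step, so
    ``beta`` solves the weighted normal equations directly.  The coefficient
    covariance is ``(X' W X)^{-1}``: when the weights are reciprocal
    dispersions 1/phi_i, the dispersion is already absorbed and no residual
    scale estimate is applied.
    """
    y = np.asarray(y, dtype=float)
    n = X.n
    if y.shape != (n,):
        raise ValueError(f"response has shape {y.shape}, expected ({n},)")
    w = np.ones(n) if w is None else _check_weights(w, n)
    beta, cov, leverage = _wls(X.values, X.column_labels, y, w)
    mu = X.values @ beta
    return MeanModelFit(
        beta=beta,
        cov_beta=cov,
        se=np.sqrt(np.diag(cov)),
        eta=mu,
        mu=mu,
        residuals=y - mu,
        d=(y - mu) ** 2,
        leverage=leverage,
        prior_weight=w,
        X=X,
    )


def deviance_components(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Gaussian deviance components d_i = (y_i - mu_i)^2."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs mu {mu.shape}")
    return (y - mu) ** 2


def fit_gamma_log(
    dresp: np.ndarray,
    G: DesignMatrix,
    w: np.ndarray | None = None,
    tol: float = GAMMA_TOL,
    max_iter: int = GAMMA_MAX_ITER,
) -> DispersionModelFit:
    """Fit a gamma-family GLM with log link by quasi-likelihood IWLS.

    The gamma variance function with a log link gives unit working weight,
    so the IWLS weight is the prior weight alone and the working response is
    ``z = xi + (d - phi)/phi``.  Zeros in the response are floored at
    ``ZERO_FLOOR_REL * mean(dresp)`` so that observations with an exactly
    zero squared residual stay in the fit.
    """
    d = np.asarray(dresp, dtype=float)
    n = G.n
    if d.shape != (n,):
        raise ValueError(f"response has shape {d.shape}, expected ({n},)")
    if np.any(d < 0):
        raise ValueError("dispersion response must be non-negative")
    dbar = float(np.mean(d)) if n else 0.0
    if dbar == 0.0:
        raise ValueError("all-zero dispersion response: dispersion is degenerate")
    w = np.ones(n) if w is None else _check_weights(w, n)
    d = np.maximum(d, ZERO_FLOOR_REL * dbar)

    xi = np.log(0.5 * (d + dbar))
    gamma = None
    trace: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        phi = np.exp(xi)
        z = xi + (d - phi) / phi
        gamma_new, cov, _ = _wls(G.values, G.column_labels, z, w)
        trace.append(gamma_new)
        delta = np.inf if gamma is None else float(np.max(np.abs(gamma_new - gamma)))
        gamma = gamma_new
        xi = G.values @ gamma
        if delta < tol:
            phi = np.exp(xi)
            return DispersionModelFit(
                gamma_coef=gamma,
                cov_gamma=cov,
                se=np.sqrt(np.diag(cov)),
                xi=xi,
                phi=phi,
                G=G,
                prior_weight=w,
                n_iter=it,
            )
    raise ConvergenceError(
        f"gamma IWLS did not converge in {max_iter} iterations", trace
    )
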