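"""Seeded synthetic cohort generator.

The original hospital cohort behind this model family is not public, so
this module generates cohorts that emulate its published summary structure:
truncated-normal covariate marginals matching the reported means, standard
deviations and observed ranges; a Gaussian copula matching the reported
pairwise Pearson correlations; a linear mean model for MUAC; and a
log-linear dispersion model, so that every downstream fitting stage has a
known ground truth.

Because truncation changes both moments and correlations, the generator
calibrates the latent Gaussian parameters so the *delivered* covariates hit
the targets: per-covariate latent (mean, sd) are solved so the truncated
marginal has the target mean and sd, and each latent pairwise correlation
is solved by Gauss-Hermite quadrature so the product-moment correlation of
the transformed pair equals the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_model import (
    COVARIATES,
    DEFAULT_TERMS,
    CohortTable,
    design_from_frame,
)

# --- Published calibration targets -------------------------------------
# Covariate moments and observed ranges of the reference cohort (n = 163
# malnourished children; age in years, height cm, weight kg, hemoglobin and
# albumen in the units reported by the source laboratory, MUAC cm).

COVARIATE_MEANS: dict[str, float] = {
    "age": 1.6334,
    "weight": 9.3894,
    "height": 78.5706,
    "hemoglobin": 10.2031,
    "protein": 65.5853,
    "albumen": 36.226,
}

COVARIATE_SDS: dict[str, float] = {
    "age": 1.18655,
    "weight": 3.90184,
    "height": 19.38403,
    "hemoglobin": 1.84967,
    "protein": 8.43823,
    "albumen": 6.5421,
}

COVARIATE_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (0.13, 5.0),
    "weight": (1.75, 20.0),
    "height": (20.0, 160.0),
    "hemoglobin": (2.1, 19.4),
    "protein": (50.0, 84.0),
    "albumen": (22.0, 48.0),
}

#: Reference MUAC summary (emergent, not enforced by the generator).
MUAC_REFERENCE = {"min": 7.4, "max": 17.5, "mean": 13.12, "sd": 1.98962}

# Pairwise Pearson correlation targets among the six covariates, in
# COVARIATES order (age, weight, height, hemoglobin, protein, albumen).
_C = {
    ("age", "weight"): 0.799,
    ("age", "height"): 0.709,
    ("age", "hemoglobin"): 0.173,
    ("age", "protein"): 0.222,
    ("age", "albumen"): 0.155,
    ("weight", "height"): 0.773,
    ("weight", "hemoglobin"): 0.250,
    ("weight", "protein"): 0.337,
    ("weight", "albumen"): 0.373,
    ("height", "hemoglobin"): 0.276,
    ("height", "protein"): 0.302,
    ("height", "albumen"): 0.268,
    ("hemoglobin", "protein"): 0.295,
    ("hemoglobin", "albumen"): 0.300,
    ("protein", "albumen"): 0.658,
}


def _corr_matrix() -> np.ndarray:
    k = len(COVARIATES)
    r = np.eye(k)
    for (a, b), v in _C.items():
        i, j = COVARIATES.index(a), COVARIATES.index(b)
        r[i, j] = r[j, i] = v
    return r


COVARIATE_CORR: np.ndarray = _corr_matrix()

#: Default mean-model coefficients (MUAC cm per unit covariate), in the
#: order of the default ten-term list.
MEAN_BETA_DEFAULT: np.ndarray = np.array(
    [
        3.514933,  # intercept
        -2.161377,  # age
        1.194023,  # weight
        0.028779,  # height
        0.033497,  # hemoglobin
        0.016998,  # protein
        0.032157,  # albumen
        -0.006908,  # weight:height
        -0.051909,  # age:weight
        0.024228,  # age:height
    ]
)

#: Default dispersion-model coefficients (log cm^2 scale), same term order.
DISPERSION_GAMMA_DEFAULT: np.ndarray = np.array(
    [
        -3.686e00,
        -4.625e-01,
        1.549e-01,
        4.431e-02,
        2.719e-01,
        -4.087e-02,
        3.496e-02,
        -3.353e-03,
        3.820e-02,
        1.095e-05,
    ]
)


class GeneratorError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    ``covariate_corr`` is the *target* product-moment correlation matrix of
    the delivered (truncated) covariates, in :data:`COVARIATES` order.
    ``mean_beta`` and ``dispersion_gamma`` are length-10 coefficient vectors
    in default term-list order (intercept first).
    """

    n: int
    seed: int
    covariate_means: dict[str, float] = field(
        default_factory=lambda: dict(COVARIATE_MEANS)
    )
    covariate_sds: dict[str, float] = field(
        default_factory=lambda: dict(COVARIATE_SDS)
    )
    covariate_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(COVARIATE_BOUNDS)
    )
    covariate_corr: np.ndarray = field(
        default_factory=lambda: COVARIATE_CORR.copy()
    )
    mean_beta: np.ndarray = field(default_factory=lambda: MEAN_BETA_DEFAULT.copy())
    dispersion_gamma: np.ndarray = field(
        default_factory=lambda: DISPERSION_GAMMA_DEFAULT.copy()
    )

    def validate(self) -> None:
        if self.n < 0:
            raise GeneratorError(f"n must be >= 0, got {self.n}")
        for k in COVARIATES:
            if k not in self.covariate_means or k not in self.covariate_sds:
                raise GeneratorError(f"missing moments for covariate {k!r}")
            if self.covariate_sds[k] <= 0:
                raise GeneratorError(f"sd for {k!r} must be positive")
            lo, hi = self.covariate_bounds[k]
            if not lo < hi:
                raise GeneratorError(f"bounds for {k!r} must satisfy min < max")
        r = np.asarray(self.covariate_corr, dtype=float)
        k = len(COVARIATES)
        if r.shape != (k, k):
            raise GeneratorError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise GeneratorError("correlation matrix must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(r)) <= 0:
            raise GeneratorError("correlation matrix is not positive definite")
        for name, vec in (("mean_beta", self.mean_beta), ("dispersion_gamma", self.dispersion_gamma)):
            if np.asarray(vec, dtype=float).shape != (DEFAULT_TERMS.p,):
                raise GeneratorError(
                    f"{name} must have length {DEFAULT_TERMS.p} (default term list)"
                )

    def override(self, updates: dict) -> "GeneratorConfig":
        """Return a copy with JSON-style field overrides applied."""
        cfg = GeneratorConfig(
            n=self.n,
            seed=self.seed,
            covariate_means=dict(self.covariate_means),
            covariate_sds=dict(self.covariate_sds),
            covariate_bounds=dict(self.covariate_bounds),
            covariate_corr=np.array(self.covariate_corr, dtype=float),
            mean_beta=np.array(self.mean_beta, dtype=float),
            dispersion_gamma=np.array(self.dispersion_gamma, dtype=float),
        )
        for key, value in updates.items():
            if key in ("covariate_means", "covariate_sds"):
                getattr(cfg, key).update({k: float(v) for k, v in value.items()})
            elif key == "covariate_bounds":
                cfg.covariate_bounds.update(
                    {k: (float(v[0]), float(v[1])) for k, v in value.items()}
                )
            elif key in ("covariate_corr", "mean_beta", "dispersion_gamma"):
                setattr(cfg, key, np.array(value, dtype=float))
            elif key in ("n", "seed"):
                setattr(cfg, key, int(value))
            else:
                raise GeneratorError(f"unknown config field {key!r}")
        return cfg


def default_config(n: int, seed: int) -> GeneratorConfig:
    """The default study-calibrated configuration."""
    if n < 0:
        raise GeneratorError(f"n must be >= 0, got {n}")
    return GeneratorConfig(n=n, seed=seed)


# --- Latent calibration -------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(48)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@lru_cache(maxsize=None)
def _latent_marginal(mean: float, sd: float, lo: float, hi: float):
    """Latent normal (m, s) whose [lo, hi]-truncation has the target moments.

    Returns (m, s, a, b) with a, b the standardized truncation limits.
    """

    def resid(params):
        m, s = params
        if s <= 0:
            return [1e6, 1e6]
        a, b = (lo - m) / s, (hi - m) / s
        mm, vv = stats.truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        return [float(mm) - mean, float(np.sqrt(vv)) - sd]

    sol = optimize.root(resid, [mean, sd], tol=1e-12)
    if not sol.success or max(abs(r) for r in resid(sol.x)) > 1e-6:
        raise GeneratorError(
            f"cannot match truncated moments mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    m, s = float(sol.x[0]), float(sol.x[1])
    return m, s, (lo - m) / s, (hi - m) / s


def _transform_nodes(marg, z):
    """Map standard-normal values through the truncated-normal marginal."""
    m, s, a, b = marg
    return stats.truncnorm.ppf(stats.norm.cdf(z), a, b, loc=m, scale=s)


@lru_cache(maxsize=None)
def _latent_rho(target: float, marg1, marg2) -> float:
    """Latent Gaussian correlation delivering the target product-moment
    correlation after both marginal transforms (2-D Gauss-Hermite)."""
    z1 = np.tile(_GH_NODES, (len(_GH_NODES), 1))
    e2 = z1.T
    w = np.outer(_GH_WEIGHTS, _GH_WEIGHTS)
    x1 = _transform_nodes(marg1, z1)
    m1 = float((w * x1).sum())
    v1 = float((w * (x1 - m1) ** 2).sum())

    def attained(rho):
        x2 = _transform_nodes(marg2, rho * z1 + np.sqrt(1.0 - rho**2) * e2)
        m2 = float((w * x2).sum())
        v2 = float((w * (x2 - m2) ** 2).sum())
        return float((w * (x1 - m1) * (x2 - m2)).sum()) / np.sqrt(v1 * v2)

    lo, hi = -0.9999, 0.9999
    if not attained(lo) <= target <= attained(hi):
        raise GeneratorError(
            f"target correlation {target} unattainable under these marginals"
        )
    return float(optimize.brentq(lambda r: attained(r) - target, lo, hi, xtol=1e-8))


def _nearest_corr(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to PD and restore unit diagonal."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() > floor:
        return r
    vals = np.clip(vals, floor, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _calibrate(config: GeneratorConfig):
    """Latent marginals and latent correlation Cholesky for a config."""
    margs = {}
    for k in COVARIATES:
        lo, hi = config.covariate_bounds[k]
        margs[k] = _latent_marginal(
            float(config.covariate_means[k]), float(config.covariate_sds[k]), float(lo), float(hi)
        )
    kdim = len(COVARIATES)
    latent = np.eye(kdim)
    for i in range(kdim):
        for j in range(i + 1, kdim):
            tgt = float(config.covariate_corr[i, j])
            if tgt == 0.0:
                rho = 0.0
            else:
                rho = _latent_rho(tgt, margs[COVARIATES[i]], margs[COVARIATES[j]])
            latent[i, j] = latent[j, i] = rho
    latent = _nearest_corr(latent)
    return margs, np.linalg.cholesky(latent)


def generate(config: GeneratorConfig) -> CohortTable:
    """Generate a synthetic cohort.

    Randomness is consumed in a fixed order from a single generator seeded
    with ``config.seed``: first the (n, 6) latent covariate normals, then
    the n response noise draws, then any redraws for the (rare) rows whose
    Gaussian response would be non-positive -- MUAC is a circumference, so
    the response is kept strictly positive by redrawing the noise for those
    rows.  Same seed and config therefore give identical tables.
    """
    config.validate()
    if config.n == 0:
        return CohortTable.empty()
    margs, chol = _calibrate(config)
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n, len(COVARIATES))) @ chol.T
    frame = pd.DataFrame(
        {k: _transform_nodes(margs[k], z[:, i]) for i, k in enumerate(COVARIATES)}
    )
    design = design_from_frame(frame, DEFAULT_TERMS)
    mu = design.values @ np.asarray(config.mean_beta, dtype=float)
    phi = np.exp(design.values @ np.asarray(config.dispersion_gamma, dtype=float))
    sigma = np.sqrt(phi)
    muac = mu + sigma * rng.standard_normal(config.n)
    for _ in range(1000):
        bad = muac <= 0
        if not bad.any():
            break
        muac[bad] = mu[bad] + sigma[bad] * rng.standard_normal(int(bad.sum()))
    else:
        raise GeneratorError(
            "could not generate a strictly positive response; the configured "
            "mean/dispersion coefficients put most response mass below zero"
        )
    frame["muac"] = muac
    return CohortTable(frame)
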