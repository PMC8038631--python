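"""Numeric data behind the standard model-checking plots.

Produces the four-panel diagnostic set for a fitted model: standardized
residuals against fitted values with a running mean, absolute residuals,
a normal quantile-quantile plot, and a residual histogram.  Rendering is an
optional thin layer (matplotlib imported lazily); the numeric bundle is the
product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .joint_glm import JointFitResult


@dataclass(frozen=True)
class DiagnosticsBundle:
    """Numeric diagnostics for one fitted model."""

    fitted: np.ndarray
    std_resid: np.ndarray
    abs_resid: np.ndarray
    running_mean: tuple[tuple[float, float], ...]
    qq: tuple[tuple[float, float], ...]
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def standardized_residuals(
    y: np.ndarray,
    mu: np.ndarray,
    phi: np.ndarray,
    leverage: np.ndarray,
) -> np.ndarray:
    """Studentized residuals r_i = (y_i - mu_i) / sqrt(phi_i (1 - q_i)).

    This is the standard GLM studentization specialized to the Gaussian
    family, with per-observation dispersion phi_i and hat-matrix leverage
    q_i.  Under the fitted model the r_i have variance close to 1.
    """
    y, mu, phi, q = (np.asarray(v, dtype=float) for v in (y, mu, phi, leverage))
    if not (y.shape == mu.shape == phi.shape == q.shape):
        raise ValueError("all inputs must have equal lengths")
    if np.any(phi <= 0):
        raise ValueError("dispersions must be strictly positive")
    if np.any(q >= 1.0) or np.any(q < 0.0):
        raise ValueError("leverages must lie in [0, 1); an exact-leverage point found")
    return (y - mu) / np.sqrt(phi * (1.0 - q))


def running_mean(
    x: np.ndarray, y: np.ndarray, window: int
) -> tuple[tuple[float, float], ...]:
    """Centered moving average of y ordered by x, shrinking at the edges.

    ``window`` must be odd and no larger than n.  Ties in x are broken by
    y so the output is independent of input row order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    n = len(x)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}]")
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    half = window // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out.append((float(xs[i]), float(np.mean(ys[lo:hi]))))
    return tuple(out)


def qq_points(r: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Normal QQ pairs: theoretical quantiles at (i - 0.5)/n vs sorted r."""
    r = np.asarray(r, dtype=float)
    n = len(r)
    if n < 2:
        raise ValueError("QQ plot requires at least two residuals")
    sample = np.sort(r)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = _sps.norm.ppf(probs)
    return tuple(zip(theo.tolist(), sample.tolist()))


def histogram_data(r: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram spanning [min r, max r]; counts sum to n."""
    r = np.asarray(r, dtype=float)
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    counts, edges = np.histogram(r, bins=bins)
    return edges, counts


def diagnostics_bundle(
    fit: JointFitResult,
    window: int | None = None,
    bins: int | None = None,
) -> DiagnosticsBundle:
    """Full diagnostic bundle for a joint fit.

    Default running-mean window is the largest odd number not exceeding
    max(5, n // 10); default bin count follows Sturges' rule.
    """
    m = fit.mean_fit
    r = standardized_residuals(
        m.mu + m.residuals, m.mu, fit.disp_fit.phi, m.leverage
    )
    n = fit.n
    if window is None:
        window = min(max(5, n // 10), n)
        if window % 2 == 0:
            window -= 1
    if bins is None:
        bins = int(np.ceil(1 + np.log2(n)))
    edges, counts = histogram_data(r, bins)
    return DiagnosticsBundle(
        fitted=m.mu,
        std_resid=r,
        abs_resid=np.abs(r),
        running_mean=running_mean(m.mu, r, window),
        qq=qq_points(r),
        hist_edges=edges,
        hist_counts=counts,
    )


def plot_diagnostics(bundle: DiagnosticsBundle, path=None):
    """Render the four-panel diagnostic figure (requires matplotlib).

    Panels: standardized residuals vs fitted with running mean, absolute
    residuals vs fitted, normal QQ, and residual histogram.  Returns the
    figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    ax = axes[0, 0]
    ax.scatter(bundle.fitted, bundle.std_resid, s=8, alpha=0.6)
    rm = np.array(bundle.running_mean)
    ax.plot(rm[:, 0], rm[:, 1], color="red", lw=1.5)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("fitted MUAC (cm)")
    ax.set_ylabel("standardized residual")

    ax = axes[0, 1]
    ax.scatter(bundle.fitted, bundle.abs_resid, s=8, alpha=0.6)
    ax.set_xlabel("fitted MUAC (cm)")
    ax.set_ylabel("|standardized residual|")

    ax = axes[1, 0]
    qq = np.array(bundle.qq)
    ax.scatter(qq[:, 0], qq[:, 1], s=8, alpha=0.6)
    lim = [qq[:, 0].min(), qq[:, 0].max()]
    ax.plot(lim, lim, color="red", lw=1.0)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("sample quantile")

    ax = axes[1, 1]
    widths = np.diff(bundle.hist_edges)
    ax.bar(bundle.hist_edges[:-1], bundle.hist_counts, width=widths, align="edge")
    ax.set_xlabel("standardized residual")
    ax.set_ylabel("count")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
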