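"""Local false discovery rate and tail-area q-values from p-value densities.

The posterior probability that a gene is null given its p-value is the local
FDR  fdr(p) = eta0 / f(p),  where f is the marginal p-value density and eta0
the null proportion.  f is estimated by the Grenander estimator: the slopes
of the least concave majorant (LCM) of the empirical CDF, the nonparametric
MLE among monotone non-increasing densities on [0, 1].  eta0 is read off as
the hull density at p -> 1 (tail-averaged for stability).  The same
machinery yields
tail-area q-values  Fdr(p) = eta0 * p / F(p)  with F the concave CDF.
"""

from __future__ import annotations

import numpy as np

__all__ = ["grenander", "local_fdr", "qvalues_grenander", "bh_adjust", "adjust_fdr"]


def grenander(p):
    """Least concave majorant of the p-value ECDF on [0, 1].

    Returns ``(knots_x, knots_F, slopes)``: the LCM touches the ECDF at the
    knots and is linear between them; ``slopes[i]`` is the (non-increasing)
    density on ``[knots_x[i], knots_x[i+1]]``.  The hull runs over the
    observed support [0, max p]; the density is extended flat beyond the
    largest p-value, so the null proportion estimate f(p -> 1) is the final
    slope rather than an artificial zero.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    x = np.sort(p)
    # ECDF at the unique support points, anchored at (0, 0)
    ux, counts = np.unique(x, return_counts=True)
    F = np.cumsum(counts) / n
    if ux[0] > 0:
        ux = np.concatenate([[0.0], ux])
        F = np.concatenate([[0.0], F])
    else:
        # p-values exactly 0 would give an infinite first slope; merge them
        # into the anchor so the hull starts at (0, 0)
        ux = np.concatenate([[0.0], ux[1:]]) if ux.size > 1 else ux
        F = np.concatenate([[0.0], F[1:]]) if F.size > 1 else F
    # upper convex hull (concave majorant): keep slopes strictly decreasing
    hx = [ux[0]]
    hF = [F[0]]
    for xi, Fi in zip(ux[1:], F[1:]):
        while len(hx) >= 2:
            s_last = (hF[-1] - hF[-2]) / (hx[-1] - hx[-2])
            s_new = (Fi - hF[-1]) / (xi - hx[-1])
            if s_new >= s_last:  # concavity violated, pop
                hx.pop()
                hF.pop()
            else:
                break
        hx.append(xi)
        hF.append(Fi)
    hx = np.asarray(hx)
    hF = np.asarray(hF)
    slopes = np.diff(hF) / np.diff(hx)
    return hx, hF, slopes


def _density_at(p, knots_x, slopes):
    """Grenander density evaluated at points p (left-continuous in segments)."""
    seg = np.clip(np.searchsorted(knots_x, p, side="left") - 1, 0, slopes.size - 1)
    return slopes[seg]


def _eta0(knots_x, knots_F, lam=0.8):
    """Null proportion: average hull density over the right tail [lam, 1].

    The raw terminal slope of the LCM is set by the gap between the last two
    order statistics and is wildly noisy; averaging the concave CDF's slope
    over the top (1 - lam) of the unit interval estimates the same limit
    f(p -> 1) stably (a hull-smoothed Storey-type estimator).
    """
    F_lam = np.interp(lam, knots_x, knots_F)
    return min(1.0, (1.0 - F_lam) / (1.0 - lam))


def local_fdr(p_values, method="grenander"):
    """Per-gene local FDR in [0, 1] from a vector of p-values.

    ``grenander`` (default) uses the monotone density estimate above;
    ``spline`` fits a smoothing spline to log histogram counts, a smoother but
    non-monotone alternative.  Needs >= 10 genes for the density estimate to
    mean anything.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("local FDR needs at least 10 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "grenander":
        kx, kF, slopes = grenander(p)
        f = _density_at(p, kx, slopes)
        # p underflowing to exactly 0 sits on the hull anchor, where the
        # decreasing-density MLE is unbounded
        f = np.where(p == 0, np.inf, f)
        eta0 = _eta0(kx, kF)
    elif method == "spline":
        f, eta0 = _spline_density(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(f > 0, eta0 / np.maximum(f, 1e-300), 1.0)
    return np.clip(fdr, 0.0, 1.0)


def _spline_density(p, n_bins=None):
    """Log-linear smoothing-spline density of p-values on a histogram."""
    from scipy.interpolate import UnivariateSpline

    n = p.size
    if n_bins is None:
        n_bins = int(np.clip(np.sqrt(n), 10, 120))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = 1.0 / n_bins
    logd = np.log((counts + 0.5) / (n * width))
    spl = UnivariateSpline(centers, logd, w=np.sqrt(counts + 0.5), k=3,
                           s=float(n_bins))
    dens = np.exp(spl(np.clip(p, centers[0], centers[-1])))
    # normalize on a fine grid so dens integrates to one
    grid = np.linspace(centers[0], centers[-1], 512)
    norm = np.trapezoid(np.exp(spl(grid)), grid)
    dens /= norm
    eta0 = float(np.exp(spl(centers[-1])) / norm)
    return dens, eta0


def qvalues_grenander(p_values):
    """Tail-area q-values  eta0 * p / F(p)  with F the concave (LCM) CDF.

    F concave with F(0) = 0 makes p / F(p) non-decreasing, so the q-values
    are automatically monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    kx, kF, slopes = grenander(p)
    seg = np.clip(np.searchsorted(kx, p, side="left") - 1, 0, slopes.size - 1)
    F = np.minimum(kF[seg] + slopes[seg] * (p - kx[seg]), 1.0)
    eta0 = _eta0(kx, kF)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(F > 0, eta0 * p / np.maximum(F, 1e-300), 0.0)
    return np.clip(q, 0.0, 1.0)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def adjust_fdr(p_values, method="grenander_q"):
    """FDR-scale q-values; ``grenander_q`` (default) or ``bh``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh" or (method == "grenander_q" and p.size < 10):
        return bh_adjust(p)
    if method == "grenander_q":
        return qvalues_grenander(p)
    raise ValueError(f"unknown method {method!r}")
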