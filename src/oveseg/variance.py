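"""Empirical-Bayes moderated variance estimation.

The per-gene within-subtype variance sigma^2(j) is assumed to follow a scaled
inverse chi-square prior sigma^2 ~ nu0 * sigma0^2 / chi2_{nu0}.  The pooled
estimator sigma_hat^2(j) (residual mean square with N - K degrees of freedom)
is shrunk toward the prior scale sigma0^2:

    sigma_tilde^2(j) = (nu0 sigma0^2 + (N - K) sigma_hat^2(j)) / (nu0 + N - K)

with the prior parameters (nu0, sigma0^2) estimated by moment matching on the
log pooled variances, exactly the fit used by limma's eBayes: under the model
sigma_hat^2 ~ sigma0^2 F(d, nu0) the mean and variance of log sigma_hat^2 are
available in closed form through digamma/trigamma functions, and nu0 solves a
monotone trigamma equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma

__all__ = [
    "VarianceModel",
    "pooled_variance",
    "estimate_prior",
    "moderate",
    "fit_variance_model",
]

#: variances below this (log2^2 units) are floored so zero-variance genes
#: keep a stable index through the weighting stage
VAR_FLOOR = 1e-12


@dataclass
class VarianceModel:
    """Pooled and moderated per-gene variances with their shared prior."""

    pooled_var: np.ndarray
    prior_df: float
    prior_var: float
    moderated_var: np.ndarray
    residual_df: int

    @property
    def moderated_sd(self) -> np.ndarray:
        return np.sqrt(self.moderated_var)

    @property
    def total_df(self) -> float:
        """Degrees of freedom of the moderated t reference, nu0 + N - K."""
        return self.prior_df + self.residual_df


def pooled_variance(data) -> np.ndarray:
    """Pooled within-subtype variance sigma_hat^2(j), df = N - K."""
    N, K = data.n_samples, data.K
    if N - K < 1:
        raise ValueError("no residual degrees of freedom (N - K = 0)")
    ss = np.zeros(data.n_genes)
    for k in range(data.K):
        block = data.values[:, data.labels == k]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return ss / (N - K)


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(pooled_var, residual_df):
    """Moment-matching estimate of the prior (nu0, sigma0^2).

    Fits the scaled-F model sigma_hat^2 ~ sigma0^2 F(d, nu0) on the log scale.
    Returns nu0 = +inf when the spread of log pooled variances does not exceed
    the sampling variance trigamma(d/2), i.e. the variances look identical.
    """
    s2 = np.asarray(pooled_var, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 genes to estimate the prior")
    if np.all(s2 <= 0):
        raise ValueError("all pooled variances are zero")
    s2 = np.maximum(s2, VAR_FLOOR)
    d = float(residual_df)
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    if evar < 1e-15:
        # exactly-equal pooled variances: no evidence of sampling scatter at
        # all, so the prior is a point mass at the common value
        return np.inf, float(np.exp(z.mean()))
    excess = evar - polygamma(1, d / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    nu0 = 2.0 * _trigamma_inverse(float(excess))
    sigma0_sq = np.exp(emean + digamma(nu0 / 2.0) - np.log(nu0 / 2.0))
    return float(nu0), float(sigma0_sq)


def moderate(pooled_var, nu0, sigma0_sq, residual_df):
    """Shrink pooled variances toward the prior scale (posterior mean)."""
    if nu0 < 0:
        raise ValueError("nu0 must be >= 0")
    if sigma0_sq <= 0:
        raise ValueError("sigma0^2 must be > 0")
    s2 = np.asarray(pooled_var, dtype=float)
    if np.isinf(nu0):
        return np.full_like(s2, sigma0_sq)
    d = float(residual_df)
    return (nu0 * sigma0_sq + d * s2) / (nu0 + d)


def fit_variance_model(data, nu0=None, sigma0_sq=None) -> VarianceModel:
    """Pooled variance + prior fit + moderation in one call.

    Passing ``nu0``/``sigma0_sq`` overrides the empirical-Bayes fit (``nu0=0``
    recovers the raw pooled variances).
    """
    s2 = pooled_variance(data)
    df = data.n_samples - data.K
    if nu0 is None or sigma0_sq is None:
        nu0_hat, sigma0_hat = estimate_prior(s2, df)
        nu0 = nu0_hat if nu0 is None else nu0
        sigma0_sq = sigma0_hat if sigma0_sq is None else sigma0_sq
    if nu0 == 0:
        mod = s2.copy()
    else:
        mod = moderate(s2, nu0, sigma0_sq, df)
    mod = np.maximum(mod, VAR_FLOOR)
    return VarianceModel(
        pooled_var=s2,
        prior_df=float(nu0),
        prior_var=float(sigma0_sq),
        moderated_var=mod,
        residual_df=df,
    )
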