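"""Per-gene test statistics: OVE-FC, OVE-sFC and the peer baselines.

OVE-FC (one-versus-everyone fold change) is the gap between the largest and
second-largest subtype means on the log2 scale,

    d_j = min_{l != (K)} { mu_(K)(j) - mu_l(j) },

where (K) is the subtype with the maximum mean.  A gene is a subtype-specific
DEG (SDEG) when d_j > 0.  The scaled statistic OVE-sFC standardizes each gap
by the moderated standard deviation,

    t_j = min_{l != (K)} (mu_(K)(j) - mu_l(j)) / (sigma_tilde(j) sqrt(1/n_(K) + 1/n_l)),

and with unequal sample sizes the minimizing l need not hold the
second-largest mean, so all l are scanned.

Baselines: one-versus-rest fold change (ratio of geometric means) and Welch
t, one-versus-one t over subtype pairs, and the one-way ANOVA F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .variance import VAR_FLOOR

__all__ = [
    "GeneStatistics",
    "subtype_means",
    "ove_fc",
    "ove_sfc",
    "ovr_fc",
    "ovr_tstat",
    "ovo_tstat",
    "anova_f",
    "gene_statistics",
]


@dataclass
class GeneStatistics:
    """Observed per-gene statistics and the subtype ranking they induce."""

    subtype_means: np.ndarray  # (G, K)
    rank_order: np.ndarray  # (G, K) subtype indices, decreasing mean
    winner: np.ndarray  # (G,) argmax subtype
    ove_fc: np.ndarray  # (G,)
    ove_sfc: np.ndarray  # (G,)
    baseline_stats: Optional[dict] = None


def subtype_means(data) -> np.ndarray:
    """Within-subtype means of log2 values, shape (n_genes, K)."""
    return group_means(data.values, data.labels, data.K)


def group_means(values, labels, K) -> np.ndarray:
    ind = np.zeros((values.shape[1], K))
    ind[np.arange(values.shape[1]), labels] = 1.0
    ind /= ind.sum(axis=0, keepdims=True)
    return values @ ind


def rank_subtypes(means) -> np.ndarray:
    """Subtype indices sorted by decreasing mean, ties by ascending index."""
    # stable sort on -means keeps ascending index order within ties
    return np.argsort(-means, axis=1, kind="stable")


def ove_fc(means):
    """OVE-FC gap d_j and the winning subtype.

    d_j is the largest mean minus the second-largest; zero when the top two
    tie (the null boundary d_j = 0).  Argmax ties break to the lowest index.
    """
    means = np.atleast_2d(means)
    order = rank_subtypes(means)
    top = np.take_along_axis(means, order[:, :2], axis=1)
    return top[:, 0] - top[:, 1], order[:, 0]


def ove_sfc(means, moderated_sd, n_k):
    """OVE-sFC statistic t_j: minimum standardized one-versus-everyone gap."""
    means = np.atleast_2d(means)
    sd = np.asarray(moderated_sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("moderated sd must be positive (variance floor failed)")
    n_k = np.asarray(n_k, dtype=float)
    winner = rank_subtypes(means)[:, 0]
    mu_top = np.take_along_axis(means, winner[:, None], axis=1)
    scale = np.sqrt(1.0 / n_k[winner][:, None] + 1.0 / n_k[None, :])
    t_all = (mu_top - means) / (sd[:, None] * scale)
    # mask the winner column out of the min
    t_all[np.arange(means.shape[0]), winner] = np.inf
    return t_all.min(axis=1)


def ovr_fc(data) -> np.ndarray:
    """One-versus-rest fold change per subtype, shape (n_genes, K).

    Ratio of geometric means, computed as 2**(mean log2 in k - mean log2 in
    the pooled rest).
    """
    means = subtype_means(data)
    n_k = data.n_k
    N = data.n_samples
    total = means @ n_k
    rest = (total[:, None] - means * n_k[None, :]) / (N - n_k)[None, :]
    return 2.0 ** (means - rest)


def ovr_tstat(data, return_p=False):
    """Welch one-versus-rest t statistic per subtype, shape (n_genes, K).

    Group-specific variance estimates enter separately, so p-values (when
    requested, two-sided) use Welch-Satterthwaite degrees of freedom.
    """
    n_k = data.n_k
    N = data.n_samples
    if np.any(n_k < 2) or np.any(N - n_k < 2):
        raise ValueError("OVR t needs >= 2 samples in each group and its rest")
    G, K = data.n_genes, data.K
    t = np.empty((G, K))
    df = np.empty((G, K))
    for k in range(K):
        ink = data.labels == k
        a = data.values[:, ink]
        b = data.values[:, ~ink]
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        na, nb = a.shape[1], b.shape[1]
        se2 = np.maximum(va / na + vb / nb, VAR_FLOOR)
        t[:, k] = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
        df[:, k] = se2**2 / np.maximum(
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1), VAR_FLOOR
        )
    if not return_p:
        return t
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def ovo_tstat(data, mode="pairwise_var", variance_model=None, correction="bonferroni",
              return_p=False):
    """One-versus-one t: minimum pairwise t of the winning subtype vs the rest.

    ``pairwise_var`` pools the variance from each subtype pair only (the
    classic OVO baseline); ``shared_var`` uses the variance model across all
    subtypes (with ``nu0 = 0`` this equals OVE-sFC with the raw pooled sd).
    One-sided pairwise p-values (upregulation in the winner) are combined by
    taking the largest over the K-1 comparisons, optionally Bonferroni-scaled.
    """
    means = subtype_means(data)
    n_k = data.n_k
    winner = rank_subtypes(means)[:, 0]
    G, K = means.shape
    if mode == "pairwise_var":
        if np.any(n_k < 2):
            raise ValueError("pairwise OVO t needs >= 2 samples per subtype")
        # pairwise pooled variances: per gene, per (winner, l) pair
        ss = np.empty((G, K))
        for k in range(K):
            block = data.values[:, data.labels == k]
            ss[:, k] = ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        t_min = np.full(G, np.inf)
        p_max = np.zeros(G)
        mu_top = np.take_along_axis(means, winner[:, None], axis=1)[:, 0]
        n_top = n_k[winner]
        ss_top = np.take_along_axis(ss, winner[:, None], axis=1)[:, 0]
        for l in range(K):
            active = winner != l
            if not active.any():
                continue
            df = n_top + n_k[l] - 2
            pooled = np.maximum((ss_top + ss[:, l]) / df, VAR_FLOOR)
            tl = (mu_top - means[:, l]) / np.sqrt(
                pooled * (1.0 / n_top + 1.0 / n_k[l])
            )
            pl = sps.t.sf(tl, df)
            t_min = np.where(active, np.minimum(t_min, tl), t_min)
            p_max = np.where(active, np.maximum(p_max, pl), p_max)
    elif mode == "shared_var":
        if variance_model is None:
            from .variance import fit_variance_model

            variance_model = fit_variance_model(data)
        t_min = ove_sfc(means, variance_model.moderated_sd, n_k)
        df_sh = variance_model.total_df
        p_max = sps.t.sf(t_min, df_sh)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not return_p:
        return t_min
    if correction == "bonferroni":
        p = np.minimum(1.0, (K - 1) * p_max)
    elif correction == "none":
        p = p_max
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return t_min, p


def anova_f(data, subtype_subset=None, variance_model=None):
    """One-way F over the given subtypes (default: all).

    Returns (F, p) per gene.  With ``variance_model=None`` this is the
    classical fixed-effects ANOVA, with the within-subset mean square in the
    denominator.  Passing a variance model gives the moderated ANOVA: the
    denominator is the empirical-Bayes moderated variance pooled across all
    subtypes, and the F reference has nu0 + N - K denominator degrees of
    freedom — the same variance that scales the OVE-sFC statistic, which is
    what makes the nested-ANOVA local FDRs powerful at small n.  Degenerate
    zero-variance genes are handled by the variance floor, so constant genes
    get F = 0 and p = 1.
    """
    subset = list(range(data.K)) if subtype_subset is None else list(subtype_subset)
    if len(subset) < 2:
        raise ValueError("ANOVA needs >= 2 subtypes")
    cols = np.isin(data.labels, subset)
    if variance_model is None:
        return _anova_from_columns(data.values[:, cols], data.labels[cols], subset)
    return _anova_from_columns(
        data.values[:, cols], data.labels[cols], subset,
        moderated_var=variance_model.moderated_var,
        df2=variance_model.total_df,
    )


def _moderated_f_pvalue(F, df1, df2):
    if np.isinf(df2):
        return sps.chi2.sf(F * df1, df1)
    return sps.f.sf(F, df1, df2)


def _anova_from_columns(values, labels, subset, moderated_var=None, df2=None):
    """Vectorized one-way F on pre-selected columns; labels in ``subset``.

    ``moderated_var`` (aligned with the rows of ``values``) switches to the
    moderated denominator with ``df2`` denominator degrees of freedom.
    """
    groups = [values[:, labels == k] for k in subset]
    sizes = np.array([g.shape[1] for g in groups])
    N = sizes.sum()
    K = len(groups)
    if N - K < 1 and moderated_var is None:
        raise ValueError("ANOVA residual df = 0")
    gmeans = np.stack([g.mean(axis=1) for g in groups], axis=1)
    grand = (gmeans * sizes).sum(axis=1) / N
    ss_between = ((gmeans - grand[:, None]) ** 2 * sizes).sum(axis=1)
    ms_between = ss_between / (K - 1)
    if moderated_var is not None:
        denom = np.maximum(moderated_var, VAR_FLOOR)
        F = ms_between / denom
        p = _moderated_f_pvalue(F, K - 1, df2)
        return F, p
    ss_within = np.zeros(values.shape[0])
    for g, m in zip(groups, gmeans.T):
        ss_within += ((g - m[:, None]) ** 2).sum(axis=1)
    ms_within = np.maximum(ss_within / (N - K), VAR_FLOOR)
    F = ms_between / ms_within
    p = sps.f.sf(F, K - 1, N - K)
    return F, p


def gene_statistics(data, variance_model, with_baselines=False) -> GeneStatistics:
    """Compute the observed OVE-FC/OVE-sFC statistics (and baselines)."""
    means = subtype_means(data)
    order = rank_subtypes(means)
    d, winner = ove_fc(means)
    t = ove_sfc(means, variance_model.moderated_sd, data.n_k)
    baselines = None
    if with_baselines:
        F, p_anova = anova_f(data)
        baselines = {
            "ovr_fc": ovr_fc(data),
            "ovr_t": ovr_tstat(data),
            "ovo_t": ovo_tstat(data),
            "anova_f": F,
            "anova_p": p_anova,
        }
    return GeneStatistics(
        subtype_means=means,
        rank_order=order,
        winner=winner,
        ove_fc=d,
        ove_sfc=t,
        baseline_stats=baselines,
    )
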