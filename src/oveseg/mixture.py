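"""Mixture null distribution of the OVE-sFC statistic via nested permutation.

Under the null (no SDEG), a gene may be a housekeeping gene or equally
upregulated in any subset of >= 2 subtypes; the null distribution of the
OVE-sFC statistic t is therefore a (K-1)-component mixture

    f(t | H0) = sum_{m=0}^{K-2} f(t | H0,m) P{H0,m | H0},

where component H0,m corresponds to equal upregulation in the top (K-m)
subtypes.  Each component is estimated by a nested permutation scheme:
sample-to-subtype labels are shuffled only among the samples of the per-gene
top (K-m) subtypes (by observed means); the bottom m subtypes keep their
labels.  m = 0 permutes all N samples, the classical ANOVA-style null.

Genes contribute permuted statistics T_{j,p} to component m with posterior
weights w_m(j) — the local FDR of an ANOVA restricted to the gene's top
(K-m) subtypes, chained per the law of total probability:

    w_0(j) = fdr_0(j),
    w_m(j) = (1 - sum_{n<m} w_n(j)) * fdr_m(j),   m = 1..K-2.

The overall p-value is the weight-averaged exceedance fraction over all
components, permutations and genes, with attainable lower bound
min_j{sum_m w_m(j)} / (P sum_m sum_j w_m(j)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .localfdr import adjust_fdr, local_fdr
from .stats import _anova_from_columns, anova_f, gene_statistics, rank_subtypes
from .variance import VAR_FLOOR, fit_variance_model

__all__ = [
    "PermutationStore",
    "NullMixture",
    "TestResult",
    "component_weights",
    "nested_permutation",
    "component_tail",
    "mixture_p",
    "subtype_specific_p",
    "adjust_fdr",
    "count_exhaustive_labelings",
]


@dataclass
class PermutationStore:
    """Permuted OVE-sFC statistics for one null component.

    ``T`` is (n_genes, P); ``win`` the argmax subtype of each permuted
    statistic, used by the subtype-specific decomposition.
    """

    m: int
    T: np.ndarray
    win: np.ndarray
    P: int


@dataclass
class NullMixture:
    weights: np.ndarray  # (G, K-1)
    component_priors: np.ndarray  # (K-1,), sums to 1
    local_fdr: np.ndarray  # (G, K-1)
    permutation_count: int
    permuted_stats: list = field(default_factory=list)
    rng_seed: Optional[int] = None


@dataclass
class TestResult:
    """Per-gene SDEG test outcome."""

    gene_ids: list
    subtypes: list
    winner: np.ndarray
    ove_fc: np.ndarray
    ove_sfc: np.ndarray
    p_overall: np.ndarray
    p_subtype: np.ndarray  # (G, K), NaN except the winner column, truncated at 1
    p_subtype_raw: np.ndarray  # pre-truncation values
    q_overall: np.ndarray
    q_subtype: np.ndarray
    p_lower_bound: float
    info: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        cols = {
            "gene_id": self.gene_ids,
            "winner": [self.subtypes[w] for w in self.winner],
            "ove_fc_log2": self.ove_fc,
            "ove_sfc": self.ove_sfc,
            "p_overall": self.p_overall,
            "q_overall": self.q_overall,
        }
        for k, lab in enumerate(self.subtypes):
            cols[f"p_{lab}"] = self.p_subtype[:, k]
        for k, lab in enumerate(self.subtypes):
            cols[f"q_{lab}"] = self.q_subtype[:, k]
        return pd.DataFrame(cols)


def component_weights(data, rank_order=None, method="grenander",
                      variance_model=None):
    """Posterior component weights w_m(j), shape (G, K-1).

    w_0 is the local FDR of the all-subtype ANOVA; deeper components use the
    ANOVA restricted to each gene's top (K-m) subtypes, with genes grouped by
    their rank-order prefix so every distinct subtype subset is tested
    coherently, and local FDR fitted on the pooled per-component p-values.
    The ANOVAs use the moderated variance across all subtypes (fitted here
    when not supplied) — the same denominator that scales the OVE-sFC
    statistic — so the nested tests keep their power at small n.

    Returns ``(weights, fdrs)``; ``fdrs`` keeps the raw local-FDR matrix.
    """
    K = data.K
    G = data.n_genes
    if variance_model is None:
        variance_model = fit_variance_model(data)
    if rank_order is None:
        from .stats import subtype_means

        rank_order = rank_subtypes(subtype_means(data))
    mod_var = variance_model.moderated_var
    df2 = variance_model.total_df
    p_mat = np.empty((G, K - 1))
    _, p_mat[:, 0] = anova_f(data, variance_model=variance_model)
    for m in range(1, K - 1):
        top = K - m
        prefix = np.sort(rank_order[:, :top], axis=1)
        # group genes by their (unordered) top subtype set
        _, inverse = np.unique(prefix, axis=0, return_inverse=True)
        pm = np.empty(G)
        for gid in np.unique(inverse):
            rows = np.flatnonzero(inverse == gid)
            subset = prefix[rows[0]]
            cols = np.isin(data.labels, subset)
            _, pm[rows] = _anova_from_columns(
                data.values[np.ix_(rows, cols)], data.labels[cols], list(subset),
                moderated_var=mod_var[rows], df2=df2,
            )
        p_mat[:, m] = pm
    fdrs = np.column_stack(
        [local_fdr(p_mat[:, m], method=method) for m in range(K - 1)]
    )
    weights = np.empty_like(fdrs)
    weights[:, 0] = fdrs[:, 0]
    remaining = 1.0 - weights[:, 0]
    for m in range(1, K - 1):
        weights[:, m] = remaining * fdrs[:, m]
        remaining = remaining - weights[:, m]
    return weights, fdrs


def count_exhaustive_labelings(n_sizes):
    """Number of distinct assignments of samples to groups of given sizes."""
    from math import factorial

    n = int(np.sum(n_sizes))
    out = factorial(n)
    for s in n_sizes:
        out //= factorial(int(s))
    return out


def _ove_sfc_perm(M, n_k, sd):
    """OVE-sFC statistic and argmax for permuted mean tensors.

    M: (G, R, K) permuted subtype means; sd: (G, R) moderated sd.
    """
    G, R, K = M.shape
    win = np.argmax(M, axis=2)
    mu_top = np.take_along_axis(M, win[:, :, None], axis=2)
    inv_n = 1.0 / np.asarray(n_k, dtype=float)
    scale = np.sqrt(inv_n[win][:, :, None] + inv_n[None, None, :])
    t_all = (mu_top - M) / (sd[:, :, None] * scale)
    np.put_along_axis(t_all, win[:, :, None], np.inf, axis=2)
    return t_all.min(axis=2), win.astype(np.int8)


def nested_permutation(data, m, P, variance_model, rng_seed=None, rng=None,
                       rank_order=None, exhaustive=False, chunk=64):
    """Permuted statistic store T_{j,p} for null component m.

    For each permutation the labels of the samples in the per-gene top
    (K - m) subtypes are shuffled uniformly at random (bottom m subtypes keep
    their labels and samples); subtype means and the moderated variance are
    recomputed per permutation with the prior (nu0, sigma0^2) frozen at its
    observed-data estimate.  ``exhaustive=True`` enumerates every distinct
    labeling instead (tiny N only) and overrides P.
    """
    if P < 1 and not exhaustive:
        raise ValueError("P must be >= 1")
    if not 0 <= m <= data.K - 2:
        raise ValueError(f"component index m={m} outside 0..K-2")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    K = data.K
    n_k = data.n_k
    N = data.n_samples
    if rank_order is None:
        from .stats import subtype_means

        rank_order = rank_subtypes(subtype_means(data))

    values = data.values
    sumsq_all = (values**2).sum(axis=1)
    obs_means = np.stack(
        [values[:, data.labels == k].mean(axis=1) for k in range(K)], axis=1
    )
    nu0, s0 = variance_model.prior_df, variance_model.prior_var
    dfres = variance_model.residual_df

    top_sets = np.sort(rank_order[:, : K - m], axis=1)
    uniq, inverse = np.unique(top_sets, axis=0, return_inverse=True)

    if exhaustive:
        # P is determined per group by enumeration and must agree across the
        # per-gene top sets (it does whenever subtype sizes are equal)
        P = None
    T = None
    win = None
    for gid in range(uniq.shape[0]):
        rows = np.flatnonzero(inverse == gid)
        subset = uniq[gid]
        in_top = np.isin(data.labels, subset)
        idx_top = np.flatnonzero(in_top)
        Xg = values[rows]
        # frozen contribution of the bottom subtypes to means
        bottom = np.setdiff1d(np.arange(K), subset)
        M_fixed = np.zeros((rows.size, K))
        for k in bottom:
            M_fixed[:, k] = obs_means[rows][:, k]
        sizes = n_k[subset]
        offsets = np.concatenate([[0], np.cumsum(sizes)])

        if exhaustive:
            from sympy.utilities.iterables import multiset_permutations

            label_seq = np.repeat(subset, sizes)
            perms = np.array(list(multiset_permutations(label_seq.tolist())))
            Pg = perms.shape[0]
            if P is None:
                P = Pg
            elif Pg != P:
                raise ValueError(
                    "exhaustive enumeration needs identical group sizes across "
                    "per-gene top sets"
                )
            if T is None:
                T = np.empty((data.n_genes, P))
                win = np.empty((data.n_genes, P), dtype=np.int8)
            for c0 in range(0, Pg, chunk):
                lab_chunk = perms[c0 : c0 + chunk]  # (C, n_top) labels
                C = lab_chunk.shape[0]
                M = np.repeat(M_fixed[:, None, :], C, axis=1)
                for j, k in enumerate(subset):
                    cols = np.array(
                        [idx_top[lab_chunk[c] == k] for c in range(C)]
                    )  # (C, n_kk)
                    M[:, :, k] = values[np.ix_(rows, cols.ravel())].reshape(
                        rows.size, C, sizes[j]
                    ).mean(axis=2)
                Tc, wc = _finish_chunk(
                    M, n_k, sumsq_all[rows], N, K, nu0, s0, dfres
                )
                T[rows, c0 : c0 + C] = Tc
                win[rows, c0 : c0 + C] = wc
        else:
            if T is None:
                T = np.empty((data.n_genes, P))
                win = np.empty((data.n_genes, P), dtype=np.int8)
            done = 0
            while done < P:
                C = min(chunk, P - done)
                perm_pos = np.stack([rng.permutation(idx_top) for _ in range(C)])
                M = np.repeat(M_fixed[:, None, :], C, axis=1)
                for j, k in enumerate(subset):
                    cols = perm_pos[:, offsets[j] : offsets[j + 1]]  # (C, n_kk)
                    M[:, :, k] = values[np.ix_(rows, cols.ravel())].reshape(
                        rows.size, C, sizes[j]
                    ).mean(axis=2)
                Tc, wc = _finish_chunk(
                    M, n_k, sumsq_all[rows], N, K, nu0, s0, dfres
                )
                T[rows, done : done + C] = Tc
                win[rows, done : done + C] = wc
                done += C
    return PermutationStore(m=m, T=T, win=win, P=P)


def _finish_chunk(M, n_k, sumsq_rows, N, K, nu0, s0, dfres):
    """Pooled/moderated variance and OVE-sFC for a chunk of permuted means."""
    n_arr = np.asarray(n_k, dtype=float)
    pooled = (sumsq_rows[:, None] - (M**2 * n_arr[None, None, :]).sum(axis=2)) / dfres
    pooled = np.maximum(pooled, 0.0)
    if np.isinf(nu0):
        mod = np.full_like(pooled, s0)
    else:
        mod = (nu0 * s0 + dfres * pooled) / (nu0 + dfres)
    sd = np.sqrt(np.maximum(mod, VAR_FLOOR))
    return _ove_sfc_perm(M, n_k, sd)


def component_tail(T_store, weights_m, t_obs):
    """Weighted exceedance fraction Pr{T > t_obs | H0,m} (strict inequality).

    ``t_obs`` may be a scalar or a vector; returns matching shape.
    """
    w = np.asarray(weights_m, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all weights zero for this component")
    vals = T_store.T.ravel()
    wts = np.repeat(w, T_store.P)
    order = np.argsort(vals, kind="stable")
    vals_sorted = vals[order]
    suffix = np.concatenate([np.cumsum(wts[order][::-1])[::-1], [0.0]])
    pos = np.searchsorted(vals_sorted, np.asarray(t_obs, dtype=float), side="right")
    return suffix[pos] / (T_store.P * wsum)


def _sorted_tally(stores, weights):
    """Pooled (value, weight/P, winner) arrays over all components, sorted.

    Each component's tally is pre-divided by its own permutation count, so
    components estimated at different P (exhaustive enumeration) combine
    correctly; with a common P this reduces to the printed single fraction.
    """
    vals, wts, wins = [], [], []
    for store in stores:
        w = weights[:, store.m]
        if w.sum() <= 0:
            continue
        vals.append(store.T.ravel())
        wts.append(np.repeat(w / store.P, store.P))
        wins.append(store.win.ravel())
    vals = np.concatenate(vals)
    wts = np.concatenate(wts)
    wins = np.concatenate(wins)
    order = np.argsort(vals, kind="stable")
    return vals[order], wts[order], wins[order]


def _exceedance(vals_sorted, wts_sorted, t_obs):
    suffix = np.concatenate([np.cumsum(wts_sorted[::-1])[::-1], [0.0]])
    pos = np.searchsorted(vals_sorted, t_obs, side="right")
    return suffix[pos]


def mixture_p(data, stats=None, variance_model=None, weights=None, P=999,
              rng_seed=None, weight_method="grenander", q_method="grenander_q",
              exhaustive=False, keep_stores=False):
    """Run the full weighted nested-permutation test; returns a TestResult.

    Components share one seeded generator (component-major stream order), the
    variance prior is estimated once from the observed data and frozen, and
    p-values are the single-fraction weighted exceedance over all components
    clamped to [lower bound, 1].
    """
    if variance_model is None:
        variance_model = fit_variance_model(data)
    if stats is None:
        stats = gene_statistics(data, variance_model)
    if weights is None:
        weights, fdrs = component_weights(
            data, rank_order=stats.rank_order, method=weight_method,
            variance_model=variance_model,
        )
    else:
        fdrs = None
    K = data.K
    G = data.n_genes

    rng = np.random.default_rng(rng_seed)
    stores = []
    for m in range(K - 1):
        if weights[:, m].sum() <= 0:
            continue
        stores.append(
            nested_permutation(
                data, m, P, variance_model, rng=rng,
                rank_order=stats.rank_order, exhaustive=exhaustive,
            )
        )
    if not stores:
        raise ValueError("every mixture component has zero total weight")
    P_eff = stores[0].P

    col_tot = weights.sum(axis=0)
    priors = np.where(col_tot > 0, col_tot, 0.0)
    priors = priors / priors.sum()
    # the tally is already divided by each component's P, so the denominator
    # is the total weight; with a common P this equals the printed
    # single-fraction form with denominator P * sum_m sum_j w_m(j)
    denom = col_tot.sum()

    vals, wts, wins = _sorted_tally(stores, weights)
    t_obs = stats.ove_sfc
    p_raw = _exceedance(vals, wts, t_obs) / denom
    inv_P = np.array([1.0 / s.P for s in stores])
    per_gene_min = (weights[:, [s.m for s in stores]] * inv_P).sum(axis=1)
    lower_bound = float(per_gene_min.min() / denom)
    p_overall = np.clip(p_raw, lower_bound, 1.0)

    p_sub_raw, p_sub = subtype_specific_p(
        t_obs, stats.winner, vals, wts, wins, K, denom, lower_bound
    )

    q_overall = adjust_fdr(p_overall, method=q_method)
    q_subtype = np.full((G, K), np.nan)
    winner_p = p_sub[np.arange(G), stats.winner]
    winner_q = adjust_fdr(winner_p, method=q_method)
    q_subtype[np.arange(G), stats.winner] = winner_q

    mixture = NullMixture(
        weights=weights,
        component_priors=priors,
        local_fdr=fdrs if fdrs is not None else weights,
        permutation_count=P_eff,
        permuted_stats=stores if keep_stores else [],
        rng_seed=rng_seed,
    )
    result = TestResult(
        gene_ids=list(data.gene_ids),
        subtypes=list(data.subtypes),
        winner=stats.winner,
        ove_fc=stats.ove_fc,
        ove_sfc=stats.ove_sfc,
        p_overall=p_overall,
        p_subtype=p_sub,
        p_subtype_raw=p_sub_raw,
        q_overall=q_overall,
        q_subtype=q_subtype,
        p_lower_bound=lower_bound,
        info={
            "nu0": variance_model.prior_df,
            "sigma0_sq": variance_model.prior_var,
            "P": P_eff,
            "seed": rng_seed,
            "component_priors": priors.tolist(),
        },
    )
    return result, mixture


def subtype_specific_p(t_obs, winner, vals_sorted, wts_sorted, wins_sorted, K,
                       denom, lower_bound=0.0):
    """Winner-conditional decomposition of the mixture p-value.

    The weighted permutation tally is restricted to permuted statistics whose
    argmax subtype equals the subtype of interest; each conditional tail
    keeps the full Eq.-7-style denominator (so the masses partition the
    overall exceedance) and is multiplied by K as the multiple-testing
    correction over subtypes.  Raw values may exceed 1 and are truncated;
    a gene receives its subtype-specific p only for its observed winner.
    """
    G = np.asarray(t_obs).size
    p_raw = np.full((G, K), np.nan)
    never_wins = []
    for s in range(K):
        mask = wins_sorted == s
        if not mask.any():
            # subtype never wins any permutation: its tally is empty
            p_raw[:, s] = 0.0
            never_wins.append(s)
            continue
        v = vals_sorted[mask]
        w = wts_sorted[mask]
        p_raw[:, s] = K * _exceedance(v, w, t_obs) / denom
    p_trunc = np.full((G, K), np.nan)
    idx = np.arange(G)
    p_trunc[idx, winner] = np.clip(p_raw[idx, winner], lower_bound, 1.0)
    for s in never_wins:
        # no permutation evidence for this subtype: record p = 1, not 0
        p_trunc[winner == s, s] = 1.0
    return p_raw, p_trunc
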