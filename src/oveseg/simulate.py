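"""Simulators for the null and power benchmark designs, plus metrics.

The null design generates only non-SDEGs: a fraction of housekeeping genes
sit at their baseline level in every subtype, and the remaining genes are
equally upregulated in a random subset of >= 2 subtypes (so the top-two gap
d_j = 0 holds for every gene before sampling noise).  Per-gene variances
follow the scaled inverse chi-square prior sigma^2 ~ nu0 sigma0^2 / chi2_nu0
and samples are Gaussian on the log2 scale.

The power design spikes in a set of true SDEGs, each upregulated in a single
subtype by a fold change drawn uniformly from a linear-scale range, on top of
the same non-SDEG background; variances come from the inverse chi-square
model or from a decreasing mean-variance trend mimicking count data.

Metrics: empirical type-I error, realized FDR/TPR at a q cutoff (a discovery
only counts as true when the subtype call is also correct), and partial AUC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "NullSimConfig",
    "PowerSimConfig",
    "SimTruth",
    "simulate_null",
    "simulate_power",
    "type1_error",
    "empirical_fdr",
    "partial_auc",
]


def _default_nk():
    return (3, 6, 9)


@dataclass
class NullSimConfig:
    """Null (type-I error) simulation settings.

    Baseline log2 means are parametric Normal(7, 2^2) clipped to [2, 14]
    unless a matrix is supplied to bootstrap from.  ``upregulation_range``
    bounds the uniform log2 mean shift shared by the upregulated subset.
    """

    n_genes: int = 10_000
    K: int = 3
    n_k: tuple = field(default_factory=_default_nk)
    housekeeping_fraction: float = 0.6
    nu0: float = 40.0
    sigma0: float = 0.5
    upregulation_range: tuple = (1.0, 4.0)
    baseline_source: str = "parametric"
    baseline_matrix: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.housekeeping_fraction <= 1.0:
            raise ValueError("housekeeping_fraction must lie in [0, 1]")
        if len(self.n_k) != self.K:
            raise ValueError("n_k must have K entries")
        if self.K < 2:
            raise ValueError("need K >= 2")


@dataclass
class PowerSimConfig:
    """Power/FDR simulation settings (defaults follow the benchmark design:
    100 SDEGs with linear fold change uniform in [5, 20])."""

    n_genes: int = 10_000
    n_sdegs: int = 100
    fc_range: tuple = (5.0, 20.0)
    K: int = 5
    n_k: tuple = (3, 3, 3, 3, 3)
    nonsdeg_pattern_ratios: Optional[dict] = None
    variance_source: str = "inverse_chi_square"
    nu0: float = 40.0
    sigma0: float = 0.5
    trend_params: tuple = (0.05, 30.0)
    upregulation_range: tuple = (1.0, 4.0)
    baseline_source: str = "parametric"
    baseline_matrix: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_sdegs >= self.n_genes:
            raise ValueError("n_sdegs must be < n_genes")
        if self.fc_range[0] <= 1.0:
            raise ValueError("fold-change lower bound must exceed 1")
        if len(self.n_k) != self.K:
            raise ValueError("n_k must have K entries")
        if self.nonsdeg_pattern_ratios is not None:
            total = sum(self.nonsdeg_pattern_ratios.values())
            if not np.isclose(total, 1.0):
                raise ValueError("nonsdeg_pattern_ratios must sum to 1")


@dataclass
class SimTruth:
    """Ground-truth gene labels for the simulators.

    ``kind`` is 'housekeeping' | 'non_sdeg' | 'sdeg'; for non-SDEGs ``m`` and
    ``subset`` record the equal-upregulation pattern, for SDEGs
    ``sdeg_subtype`` and ``true_fc`` (linear scale) record the spike.
    """

    kind: np.ndarray
    m: np.ndarray
    subset: list
    sdeg_subtype: np.ndarray
    true_fc: np.ndarray

    @property
    def is_sdeg(self) -> np.ndarray:
        return self.kind == "sdeg"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(self.kind.size)],
                "kind": self.kind,
                "m": self.m,
                "subset": ["+".join(map(str, s)) if s else "" for s in self.subset],
                "sdeg_subtype": self.sdeg_subtype,
                "true_fc": self.true_fc,
            }
        )

    @classmethod
    def from_frame(cls, df):
        subset = [
            tuple(int(x) for x in str(s).split("+")) if str(s) not in ("", "nan") else ()
            for s in df["subset"]
        ]
        return cls(
            kind=df["kind"].to_numpy(dtype=object),
            m=df["m"].to_numpy(dtype=int),
            subset=subset,
            sdeg_subtype=df["sdeg_subtype"].to_numpy(dtype=int),
            true_fc=df["true_fc"].to_numpy(dtype=float),
        )


def _baseline_means(n_genes, source, matrix, rng):
    if source == "parametric":
        return np.clip(rng.normal(7.0, 2.0, size=n_genes), 2.0, 14.0)
    if source == "bootstrap":
        if matrix is None:
            raise ValueError("bootstrap baseline needs a matrix")
        row_means = np.asarray(matrix, dtype=float).mean(axis=1)
        return row_means[rng.integers(0, row_means.size, size=n_genes)]
    raise ValueError(f"unknown baseline_source {source!r}")


def _all_patterns(K):
    """All (m, subset) equal-upregulation patterns with |subset| = K - m >= 2."""
    out = []
    for m in range(K - 1):
        for subset in itertools.combinations(range(K), K - m):
            out.append((m, subset))
    return out


def _invchisq_variances(n_genes, nu0, sigma0, rng):
    return nu0 * sigma0**2 / rng.chisquare(nu0, size=n_genes)


def _sample_matrix(mu, sigma, n_k, rng):
    """Draw Gaussian log2 samples; mu (G, K), sigma (G,)."""
    cols = np.repeat(np.arange(len(n_k)), n_k)
    return rng.normal(mu[:, cols], sigma[:, None])


def _package(X, n_k, seed_tag):
    K = len(n_k)
    sample_ids, subtype_of = [], {}
    for k in range(K):
        for i in range(n_k[k]):
            sid = f"S{k}_{i}"
            sample_ids.append(sid)
            subtype_of[sid] = f"S{k}"
    return ExpressionDataset(
        values=X,
        gene_ids=[f"g{i}" for i in range(X.shape[0])],
        sample_ids=sample_ids,
        subtype_of=subtype_of,
    )


def simulate_null(config: NullSimConfig):
    """Generate a null dataset (every gene has top-two gap d_j = 0)."""
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, config.K
    base = _baseline_means(G, config.baseline_source, config.baseline_matrix, rng)
    mu = np.tile(base[:, None], (1, K))

    n_hk = int(round(config.housekeeping_fraction * G))
    hk = np.zeros(G, dtype=bool)
    hk[rng.choice(G, size=n_hk, replace=False)] = True

    patterns = _all_patterns(K)
    kind = np.where(hk, "housekeeping", "non_sdeg").astype(object)
    m_arr = np.zeros(G, dtype=int)
    subset_list = [()] * G
    lo, hi = config.upregulation_range
    for j in np.flatnonzero(~hk):
        m, subset = patterns[rng.integers(0, len(patterns))]
        shift = rng.uniform(lo, hi)
        mu[j, list(subset)] += shift
        m_arr[j] = m
        subset_list[j] = subset

    sigma2 = _invchisq_variances(G, config.nu0, config.sigma0, rng)
    X = _sample_matrix(mu, np.sqrt(sigma2), config.n_k, rng)
    data = _package(X, config.n_k, config.seed)
    truth = SimTruth(
        kind=kind,
        m=m_arr,
        subset=subset_list,
        sdeg_subtype=np.full(G, -1, dtype=int),
        true_fc=np.full(G, np.nan),
    )
    return data, truth


def simulate_power(config: PowerSimConfig):
    """Generate a dataset with spiked SDEGs on a non-SDEG background."""
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, config.K
    base = _baseline_means(G, config.baseline_source, config.baseline_matrix, rng)
    mu = np.tile(base[:, None], (1, K))

    kind = np.full(G, "non_sdeg", dtype=object)
    m_arr = np.zeros(G, dtype=int)
    subset_list = [()] * G
    sdeg_subtype = np.full(G, -1, dtype=int)
    true_fc = np.full(G, np.nan)

    sdeg_idx = rng.choice(G, size=config.n_sdegs, replace=False)
    # round-robin winner assignment keeps subtypes balanced within +/- 1
    winners = np.arange(config.n_sdegs) % K
    fcs = rng.uniform(*config.fc_range, size=config.n_sdegs)
    for j, w, fc in zip(sdeg_idx, winners, fcs):
        mu[j, w] += np.log2(fc)
        kind[j] = "sdeg"
        sdeg_subtype[j] = w
        true_fc[j] = fc

    # background patterns: housekeeping plus all equal-upregulation subsets
    patterns = [("housekeeping", ())] + _all_patterns(K)
    if config.nonsdeg_pattern_ratios is None:
        probs = np.full(len(patterns), 1.0 / len(patterns))
    else:
        keys = ["housekeeping"] + [p for p in _all_patterns(K)]
        probs = np.array([config.nonsdeg_pattern_ratios.get(k, 0.0) for k in keys])
        probs = probs / probs.sum()
    lo, hi = config.upregulation_range
    bg = np.setdiff1d(np.arange(G), sdeg_idx)
    choices = rng.choice(len(patterns), size=bg.size, p=probs)
    for j, c in zip(bg, choices):
        pat = patterns[c]
        if pat[0] == "housekeeping":
            kind[j] = "housekeeping"
        else:
            m, subset = pat
            mu[j, list(subset)] += rng.uniform(lo, hi)
            m_arr[j] = m
            subset_list[j] = subset

    if config.variance_source == "inverse_chi_square":
        sigma2 = _invchisq_variances(G, config.nu0, config.sigma0, rng)
    elif config.variance_source == "mean_variance_trend":
        a, b = config.trend_params
        sigma2 = a + b * 2.0 ** (-base)
        # lognormal scatter around the trend keeps gene-to-gene spread
        sigma2 = sigma2 * np.exp(rng.normal(0.0, 0.4, size=G))
    else:
        raise ValueError(f"unknown variance_source {config.variance_source!r}")

    X = _sample_matrix(mu, np.sqrt(sigma2), config.n_k, rng)
    data = _package(X, config.n_k, config.seed)
    truth = SimTruth(
        kind=kind, m=m_arr, subset=subset_list,
        sdeg_subtype=sdeg_subtype, true_fc=true_fc,
    )
    return data, truth


def type1_error(result, truth, alpha=0.05):
    """Overall and per-winning-subtype rejection rates on null data."""
    if truth.is_sdeg.any():
        raise ValueError("type-I error is only defined on null data")
    reject = result.p_overall < alpha
    out = {"overall": float(reject.mean()), "per_subtype": {}}
    for k, lab in enumerate(result.subtypes):
        mask = result.winner == k
        out["per_subtype"][lab] = float(reject[mask].mean()) if mask.any() else np.nan
    return out


def empirical_fdr(result, truth, q_cutoff=0.05):
    """Realized FDR and TPR at a q cutoff; correct subtype call required."""
    if not truth.is_sdeg.any():
        raise ValueError("empirical FDR needs data containing true SDEGs")
    disc = result.q_overall < q_cutoff
    n_disc = int(disc.sum())
    true_hit = disc & truth.is_sdeg & (result.winner == truth.sdeg_subtype)
    n_true = int(true_hit.sum())
    if n_disc == 0:
        return {"fdr": 0.0, "tpr": 0.0, "n_discoveries": 0, "no_discoveries": True}
    return {
        "fdr": float((n_disc - n_true) / n_disc),
        "tpr": float(n_true / truth.is_sdeg.sum()),
        "n_discoveries": n_disc,
        "no_discoveries": False,
    }


def partial_auc(scores, truth, fpr_max=0.01):
    """Partial AUC over FPR in [0, fpr_max], normalized to [0, 1].

    ``truth`` may be a SimTruth or a boolean label vector (True = SDEG).
    Higher score = more SDEG-like.
    """
    y = truth.is_sdeg if hasattr(truth, "is_sdeg") else np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both classes present")
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError("fpr_max must lie in (0, 1]")
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y.astype(int), scores)
    # interpolate the curve at fpr_max and integrate the clipped segment
    if fpr_max < fpr[-1]:
        tpr_at = np.interp(fpr_max, fpr, tpr)
        keep = fpr <= fpr_max
        fx = np.concatenate([fpr[keep], [fpr_max]])
        fy = np.concatenate([tpr[keep], [tpr_at]])
    else:
        fx, fy = fpr, tpr
    return float(np.trapezoid(fy, fx) / fpr_max)
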