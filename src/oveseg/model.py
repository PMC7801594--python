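"""Model/Results front door for the OVE-sFC SDEG test.

Usage mirrors the statsmodels idiom::

    model = OVESFC(dataset)                     # or OVESFC.from_dataframe(...)
    res = model.fit(permutations=999, seed=1)
    print(res.summary())
    res.save("results.tsv")
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, write_results
from .mixture import component_weights, mixture_p
from .stats import gene_statistics
from .variance import fit_variance_model

__all__ = ["OVESFC", "OVESFCResults"]


class OVESFC:
    """One-Versus-Everyone scaled fold-change test for SDEG detection.

    Parameters
    ----------
    data : ExpressionDataset
        Log2 expression with a subtype design (K >= 2).
    nu0, sigma0_sq : float, optional
        Override the empirical-Bayes variance prior (``nu0=0`` disables
        moderation); by default both are estimated from the pooled variances.
    """

    def __init__(self, data: ExpressionDataset, nu0=None, sigma0_sq=None):
        self.data = data
        self.variance_model = fit_variance_model(data, nu0=nu0, sigma0_sq=sigma0_sq)
        self.stats = gene_statistics(data, self.variance_model)
        self._weights = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, design, **kwargs) -> "OVESFC":
        """Build from a genes x samples DataFrame and a design.

        ``design`` maps sample id -> subtype label (dict or Series).
        """
        if isinstance(design, pd.DataFrame):
            design = dict(zip(design.iloc[:, 0].astype(str), design.iloc[:, 1]))
        elif isinstance(design, pd.Series):
            design = design.to_dict()
        data = ExpressionDataset(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            subtype_of={str(k): str(v) for k, v in design.items()},
        )
        return cls(data, **kwargs)

    @property
    def weights(self) -> np.ndarray:
        """Posterior null-component weights w_m(j), computed lazily."""
        if self._weights is None:
            self._weights, self._fdrs = component_weights(
                self.data, rank_order=self.stats.rank_order,
                variance_model=self.variance_model,
            )
        return self._weights

    def fit(self, permutations: int = 999, seed: Optional[int] = None,
            q_method: str = "grenander_q", exhaustive: bool = False,
            keep_stores: bool = False) -> "OVESFCResults":
        """Estimate the mixture null by nested permutation and test all genes."""
        result, mixture = mixture_p(
            self.data,
            stats=self.stats,
            variance_model=self.variance_model,
            weights=self.weights,
            P=permutations,
            rng_seed=seed,
            q_method=q_method,
            exhaustive=exhaustive,
            keep_stores=keep_stores,
        )
        return OVESFCResults(self, result, mixture)


class OVESFCResults:
    """Fitted OVE-sFC test: per-gene statistics, p/q-values, diagnostics."""

    def __init__(self, model, result, mixture):
        self.model = model
        self._result = result
        self.mixture = mixture
        # per-gene arrays, statsmodels-style flat attributes
        self.subtypes = result.subtypes
        self.gene_ids = result.gene_ids
        self.ove_fc = result.ove_fc
        self.ove_sfc = result.ove_sfc
        self.winner = result.winner
        self.p_overall = result.p_overall
        self.q_overall = result.q_overall
        self.p_subtype = result.p_subtype
        self.q_subtype = result.q_subtype
        self.p_subtype_raw = result.p_subtype_raw
        self.p_lower_bound = result.p_lower_bound
        self.component_priors = mixture.component_priors

    @property
    def result(self):
        return self._result

    def to_frame(self) -> pd.DataFrame:
        return self._result.to_frame()

    def save(self, path) -> None:
        write_results(self._result, path)

    def significant(self, q_cutoff: float = 0.05) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[frame["q_overall"] < q_cutoff].sort_values("p_overall")

    def summary(self, top: int = 10) -> str:
        vm = self.model.variance_model
        data = self.model.data
        lines = []
        lines.append("OVE-sFC subtype-specific DEG test")
        lines.append("=" * 64)
        lines.append(f"genes: {data.n_genes}    samples: {data.n_samples}"
                     f"    subtypes (K): {data.K}")
        lines.append(f"samples per subtype: "
                     + ", ".join(f"{s}={n}" for s, n in zip(data.subtypes, data.n_k)))
        nu0 = vm.prior_df
        nu0_str = "inf" if np.isinf(nu0) else f"{nu0:.3g}"
        lines.append(f"variance prior: nu0 = {nu0_str}, sigma0^2 = {vm.prior_var:.4g}"
                     f"    residual df = {vm.residual_df}")
        lines.append(f"permutations P = {self.mixture.permutation_count}"
                     f"    p lower bound = {self.p_lower_bound:.3g}")
        pr = ", ".join(f"H0,{m}: {p:.3f}"
                       for m, p in enumerate(self.component_priors))
        lines.append(f"mixture component priors: {pr}")
        n_sig = int((self.q_overall < 0.05).sum())
        lines.append(f"genes with q < 0.05: {n_sig}")
        lines.append("-" * 64)
        frame = self.to_frame().sort_values("p_overall").head(top)
        lines.append(frame.to_string(
            index=False,
            columns=["gene_id", "winner", "ove_fc_log2", "ove_sfc",
                     "p_overall", "q_overall"],
            float_format=lambda v: f"{v:.4g}",
        ))
        return "\n".join(lines)

    def __repr__(self):
        return (f"<OVESFCResults: {len(self.p_overall)} genes, "
                f"K={self.model.data.K}, P={self.mixture.permutation_count}>")
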