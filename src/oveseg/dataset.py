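"""Expression-matrix containers and text-table I/O.

The universal input is a genes x samples matrix of expression values together
with a design mapping each sample to a purified subtype.  All internal
computation is on the log2 scale; linear-scale input is log-transformed with a
pseudocount on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneFilterReport",
    "load_expression",
    "filter_low_expression",
    "write_results",
]


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with a sample-to-subtype design.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Log2-scale expression values; must be finite.
    gene_ids : list of str
        Unique gene/probe identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    subtype_of : dict
        Maps every sample id to its subtype label.
    raw_scale_flag : bool
        True when the input was linear-scale and log2-transformed on load.

    Notes
    -----
    Subtype labels are ordered by first appearance in ``sample_ids`` and
    exposed through ``subtypes``; ``labels`` holds the integer subtype index
    of each sample column.  Gene and sample order is never re-sorted, so the
    permutation streams downstream are reproducible.
    """

    values: np.ndarray
    gene_ids: list
    sample_ids: list
    subtype_of: dict
    log_base: int = 2
    raw_scale_flag: bool = False
    subtypes: list = field(init=False)
    labels: np.ndarray = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.subtype_of]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        # subtype order = first appearance among sample columns
        seen = {}
        for s in self.sample_ids:
            lab = self.subtype_of[s]
            if lab not in seen:
                seen[lab] = len(seen)
        self.subtypes = list(seen)
        if len(self.subtypes) < 2:
            raise ValueError("need at least K = 2 subtypes")
        self.labels = np.array(
            [seen[self.subtype_of[s]] for s in self.sample_ids], dtype=np.intp
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def K(self) -> int:
        """Number of subtypes."""
        return len(self.subtypes)

    @property
    def n_k(self) -> np.ndarray:
        """Samples per subtype, in subtype order."""
        return np.bincount(self.labels, minlength=self.K)

    def subset_genes(self, index) -> "ExpressionDataset":
        """Return a new dataset restricted to the given gene rows."""
        index = np.asarray(index)
        return ExpressionDataset(
            values=self.values[index],
            gene_ids=[self.gene_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            subtype_of=dict(self.subtype_of),
            raw_scale_flag=self.raw_scale_flag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneFilterReport:
    """Bookkeeping for the optional low-expression pre-filter."""

    kept: np.ndarray
    dropped_low_expression: np.ndarray
    threshold: float

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=np.intp)
        self.dropped_low_expression = np.asarray(
            self.dropped_low_expression, dtype=np.intp
        )


def load_expression(matrix_path, design_path, input_scale="log2", pseudocount=1.0):
    """Read an expression table and its design into an :class:`ExpressionDataset`.

    The matrix is TSV/CSV with a header row of sample ids and gene ids in the
    first column; the design is a two-column table (sample_id, subtype).
    ``input_scale='linear'`` applies ``log2(x + pseudocount)``.
    """
    sep_m = "," if str(matrix_path).endswith(".csv") else "\t"
    sep_d = "," if str(design_path).endswith(".csv") else "\t"
    mat = pd.read_csv(matrix_path, sep=sep_m, index_col=0)
    design = pd.read_csv(design_path, sep=sep_d)
    if design.shape[1] < 2:
        raise ValueError("design must have columns (sample_id, subtype)")
    subtype_of = dict(zip(design.iloc[:, 0].astype(str), design.iloc[:, 1].astype(str)))

    sample_ids = [str(c) for c in mat.columns]
    unknown = [s for s in subtype_of if s not in set(sample_ids)]
    if unknown:
        raise ValueError(f"design contains samples absent from the matrix: {unknown}")
    absent = [s for s in sample_ids if s not in subtype_of]
    if absent:
        raise ValueError(f"matrix samples absent from the design: {absent}")

    values = mat.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN")
    raw = False
    if input_scale == "linear":
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if (values < 0).any():
            raise ValueError("negative values in linear-scale matrix")
        values = np.log2(values + pseudocount)
        raw = True
    elif input_scale != "log2":
        raise ValueError(f"unknown input_scale {input_scale!r}")

    return ExpressionDataset(
        values=values,
        gene_ids=[str(g) for g in mat.index],
        sample_ids=sample_ids,
        subtype_of=subtype_of,
        raw_scale_flag=raw,
    )


def filter_low_expression(data, floor, min_subtypes_above=1):
    """Drop genes whose subtype means exceed ``floor`` (log2) in fewer than
    ``min_subtypes_above`` subtypes.

    Returns the filtered dataset and a :class:`GeneFilterReport` that accounts
    for every input gene.  Raises if nothing survives.
    """
    means = np.stack(
        [data.values[:, data.labels == k].mean(axis=1) for k in range(data.K)], axis=1
    )
    above = (means > floor).sum(axis=1)
    keep = above >= min_subtypes_above
    report = GeneFilterReport(
        kept=np.flatnonzero(keep),
        dropped_low_expression=np.flatnonzero(~keep),
        threshold=float(floor),
    )
    if not keep.any():
        err = ValueError("low-expression filter removed every gene")
        err.report = report
        raise err
    return data.subset_genes(report.kept), report


def write_results(result, path) -> None:
    """Serialize a test result, one row per gene, as TSV.

    Columns: gene id, winning subtype, OVE-FC (log2), OVE-sFC, overall p/q,
    and per-subtype p and q columns.  Round-trip readable with
    ``pandas.read_csv(path, sep='\\t')``.
    """
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
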