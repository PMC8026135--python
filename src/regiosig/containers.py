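"""Shared in-memory containers for count data, DE results and gene sets.

The central substrate is :class:`CountMatrix`, an integer gene x sample
(or gene x cell) matrix with per-column annotations (region, cell type,
thalamic nucleus, animal; plus total UMIs and mitochondrial fraction for
single-cell data). Differential-expression runs produce a :class:`DEResult`
whose filtered outputs are :class:`GeneSet` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """A configuration value violated its documented constraint."""


#: Closed vocabulary of first-order sensory thalamic nuclei, in the fixed
#: order used for tie-breaking throughout the package.
NUCLEI = ("dLG", "VPM", "MGv")


@dataclass
class CountMatrix:
    """Integer count matrix (genes x samples) with column annotations.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers, one per row.
    samples
        DataFrame indexed by sample/cell id, one row per column of
        ``counts``. Typical columns: ``region``, ``cell_type``, ``nucleus``,
        ``animal``; single-cell matrices add ``total_umis`` and
        ``mito_fraction``.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ConfigError("counts must be a 2-D array")
        if np.any(self.counts < 0):
            raise ConfigError("counts must be non-negative")
        self.gene_ids = pd.Index(self.gene_ids)
        if self.gene_ids.has_duplicates:
            raise ConfigError("gene_ids must be unique")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ConfigError("gene_ids length must match count rows")
        if len(self.samples) != self.counts.shape[1]:
            raise ConfigError("sample annotations must cover every column")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def column_indices(self, sample_ids) -> np.ndarray:
        idx = self.samples.index.get_indexer(list(sample_ids))
        if np.any(idx < 0):
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"unknown sample ids: {missing}")
        return idx

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = self.column_indices(sample_ids)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            samples=self.samples.iloc[idx],
        )

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = self.gene_ids.get_indexer(list(gene_ids))
        if np.any(idx < 0):
            raise KeyError("unknown gene ids in subset")
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            samples=self.samples,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples.index)


@dataclass
class SizeFactors:
    """Per-sample scaling constants from the median-of-ratios method."""

    factors: np.ndarray
    sample_ids: pd.Index
    n_reference_genes: int

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(~np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ConfigError("size factors must be finite and > 0")
        if len(self.factors) != len(self.sample_ids):
            raise ConfigError("one size factor per sample required")


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for a two-group contrast.

    ``table`` is indexed by gene id with columns ``log2fc`` (group B over
    group A for the count-based Wald test; natural-log A over B for the
    single-cell rank-sum test, stored in ``logfc``), group means, dispersion,
    the test statistic, ``p_raw`` and BH-adjusted ``p_adj``, and detection
    fractions ``pct_a`` / ``pct_b`` (single-cell only, else NaN).
    """

    table: pd.DataFrame
    group_a: tuple
    group_b: tuple
    method: str

    def __post_init__(self) -> None:
        for col in ("p_raw", "p_adj"):
            p = self.table[col].to_numpy(dtype=float)
            finite = p[np.isfinite(p)]
            if np.any((finite < 0) | (finite > 1)):
                raise ConfigError(f"{col} outside [0, 1]")


@dataclass
class GeneSet:
    """A named, ordered, duplicate-free list of gene identifiers."""

    name: str
    genes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = list(self.genes)
        if len(set(genes)) != len(genes):
            raise ConfigError(f"gene set {self.name!r} contains duplicates")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)

    def intersection(self, other: "GeneSet") -> set:
        return set(self.genes) & set(other.genes)
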