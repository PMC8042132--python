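"""Quantile normalization, gene-gene Pearson correlation, and KNN sets.

The co-expression front end: samples are quantile-normalized to a common
reference distribution (the per-rank mean of sorted sample vectors), a full
gene-gene Pearson correlation matrix is computed, and each gene's K most
positively correlated partners are extracted as its KNN set (default K=40).

Neighbor ranking uses signed r, not |r|: the KNN set is the "most highly
correlated" genes, i.e. top positive correlation. Set ``absolute=True`` on
:func:`knn_neighbors` to rank by magnitude instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from guiltnet.io import validate_expression

DEFAULT_K = 40


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the per-rank-mean reference distribution.

    The reference vector is the mean, at each rank, of the sorted sample
    vectors. Each sample's values are replaced by the reference value at
    their rank; tied values within a sample receive the mean of the
    reference values at the tied ranks.

    Raises ``ValueError`` for single-sample input (undefined) and on missing
    values.
    """
    validate_expression(expr)
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization requires >=2 samples")
    values = expr.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        mapped = np.empty_like(sorted_col)
        i = 0
        n = len(sorted_col)
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            mapped[i : k + 1] = reference[i : k + 1].mean()  # tie rule
            i = k + 1
        out[order, j] = mapped
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix.

    ``zero_variance`` lists genes with no sample variance; their r against
    every other gene is defined as 0 (diagonal stays 1) so the matrix is
    total and the KNN step deterministic.
    """

    gene_ids: list[str]
    r: np.ndarray
    zero_variance: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.gene_ids, columns=self.gene_ids)


def correlation_matrix(expr: pd.DataFrame) -> CorrelationMatrix:
    """Sample Pearson correlation of every gene pair (rows of ``expr``)."""
    validate_expression(expr)
    if expr.shape[1] < 3:
        raise ValueError("correlation requires >=3 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = sd == 0
    zero_variance = [g for g, z in zip(expr.index, flat) if z]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(list(expr.index), r, zero_variance)


@dataclass
class NeighborList:
    """Per-gene ordered lists of the K most correlated partners."""

    k: int
    neighbors: dict[str, list[tuple[str, float]]]

    def __getitem__(self, gene: str) -> list[tuple[str, float]]:
        return self.neighbors[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.neighbors

    def query_set(self, gene: str) -> list[str]:
        """Neighbor ids of ``gene``, excluding the gene itself."""
        return [g for g, _ in self.neighbors[gene] if g != gene]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gene, rank, nb, r)
            for gene, lst in self.neighbors.items()
            for rank, (nb, r) in enumerate(lst, start=1)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "rank", "neighbor_id", "r"])


def knn_neighbors(
    corr: CorrelationMatrix, k: int = DEFAULT_K, *, absolute: bool = False
) -> NeighborList:
    """K nearest neighbors of each gene by correlation.

    Self is excluded; exact ties in r are broken by ascending lexicographic
    gene id; lists are truncated to n_genes - 1 when K exceeds it.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    genes = corr.gene_ids
    n = len(genes)
    kept = min(k, n - 1)
    key = np.abs(corr.r) if absolute else corr.r
    neighbors: dict[str, list[tuple[str, float]]] = {}
    for i, gene in enumerate(genes):
        candidates = [(-key[i, j], genes[j], corr.r[i, j]) for j in range(n) if j != i]
        candidates.sort()
        neighbors[gene] = [(g, r) for _, g, r in candidates[:kept]]
    return NeighborList(kept, neighbors)
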