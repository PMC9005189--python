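"""G-protein tissue expression profiling and co-expression clustering.

Works on a gene x tissue matrix of nTPM values (Human Protein Atlas
consensus dialect, read by :func:`couplemap.data_io.read_expression_table`).
Conventions that the printed statistics depend on are fixed here and
recorded in results: percentiles use linear interpolation, z-scores use
the population (n) standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "quartile_threshold",
    "tissues_above_threshold",
    "zscore_per_gene",
    "coexpression_cluster",
    "display_cap",
    "aggregate_tissues",
]


def quartile_threshold(matrix: pd.DataFrame) -> float:
    """First quartile of all matrix values (linear-interpolation percentile)."""
    values = matrix.to_numpy(dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty expression matrix")
    return float(np.percentile(values, 25))


def tissues_above_threshold(matrix: pd.DataFrame, threshold: float) -> pd.Series:
    """Per gene: number of tissues with expression >= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return (matrix >= threshold).sum(axis=1)


def zscore_per_gene(matrix: pd.DataFrame):
    """Row-wise z-scores with population SD.

    Returns ``(z, flagged)`` where ``flagged`` lists constant genes whose
    z-scores are undefined (rows left NaN).
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flagged = [g for g, s in zip(matrix.index, sd.ravel()) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[sd.ravel() == 0, :] = np.nan
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def coexpression_cluster(matrix: pd.DataFrame):
    """Gene x gene Pearson correlation of tissue profiles plus display order.

    Constant genes are excluded (correlation undefined) and reported.
    Returns ``(corr, order, excluded)``; ``order`` is the average-linkage
    dendrogram leaf order on correlation distance.
    """
    sd = matrix.std(axis=1, ddof=0)
    excluded = list(matrix.index[sd == 0])
    keep = matrix.loc[sd > 0]
    corr = keep.T.corr(method="pearson")
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    order = [keep.index[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order, excluded


def display_cap(matrix: pd.DataFrame) -> float:
    """Median over genes of each gene's maximum expression (heatmap cap)."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    return float(matrix.max(axis=1).median())


def aggregate_tissues(matrix: pd.DataFrame, tissue_to_group: dict,
                      how: str = "mean") -> pd.DataFrame:
    """Aggregate tissue columns into organ/system groups (mean or max)."""
    missing = sorted(set(matrix.columns) - set(tissue_to_group))
    if missing:
        raise ValueError(f"tissues without a group: {missing}")
    groups = matrix.T.groupby(matrix.columns.map(tissue_to_group))
    agg = groups.mean() if how == "mean" else groups.max()
    return agg.T
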