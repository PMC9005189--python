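"""G protein x G protein co-coupling matrices and the correlation tree.

Each G protein is represented by its vector of harmonized activity
values -- log(Emax/EC50), an average of the per-source averages where
both quantitative sources contribute -- over a common receptor set.
Three complementary comparisons are computed:

* Pearson correlation on zero-filled vectors (a non-coupler is an
  explicit 0, the one analysis where zeros are meaningful);
* Jaccard index of the coupled receptor sets (shared coupling);
* mean absolute difference of activity over co-coupled receptors.

The overall correlation structure is summarized by average-linkage
hierarchical clustering on the correlation distance 1 - r.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "coupling_vectors",
    "pearson_matrix",
    "significance_stars",
    "jaccard_matrix",
    "activation_difference",
    "correlation_tree",
    "linkage_to_newick",
]


def coupling_vectors(map_df: pd.DataFrame, receptors=None,
                     zero_fill: bool = True,
                     subtypes=None) -> pd.DataFrame:
    """Receptor x G-protein matrix of supported map values.

    ``map_df`` is the unified map (quantitative section); its
    ``map_value`` already averages the available sources.  With
    ``zero_fill`` non-couplers become 0 (for the Pearson analysis);
    otherwise they stay NaN (for Jaccard / activation differences).
    """
    sub = map_df[(map_df["section"] == "quantitative")
                 & map_df["gprotein"].notna()]
    grid = sub.pivot_table(index="receptor", columns="gprotein",
                           values="map_value", aggfunc="mean")
    if receptors is not None:
        grid = grid.reindex(index=sorted(set(receptors)))
    if subtypes is not None:
        grid = grid.reindex(columns=[s for s in subtypes])
    if zero_fill:
        grid = grid.fillna(0.0)
    return grid


def pearson_matrix(vectors: pd.DataFrame):
    """Pairwise Pearson r and two-tailed p over zero-filled vectors.

    Constant vectors give NaN (undefined correlation).  Vectors must
    have length >= 3 for a meaningful p-value.
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 receptors for correlation")
    units = list(vectors.columns)
    n = len(units)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = vectors.iloc[:, i].to_numpy(dtype=float)
            y = vectors.iloc[:, j].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=units, columns=units)
    p_df = pd.DataFrame(p, index=units, columns=units)
    return r_df, p_df


def significance_stars(p: float) -> str:
    """Raw two-tailed significance stars (no multiplicity correction)."""
    if not np.isfinite(p):
        return ""
    if p <= 0.0005:
        return "***"
    if p <= 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def jaccard_matrix(coupled_sets: dict) -> pd.DataFrame:
    """Jaccard index |A&B| / |A|B| per G-protein pair of coupled-receptor sets."""
    units = list(coupled_sets)
    out = pd.DataFrame(np.nan, index=units, columns=units)
    for i, a in enumerate(units):
        for j, b in enumerate(units):
            sa, sb = set(coupled_sets[a]), set(coupled_sets[b])
            union = sa | sb
            if union:
                out.iloc[i, j] = len(sa & sb) / len(union)
    return out


def activation_difference(vectors: pd.DataFrame) -> pd.DataFrame:
    """|mean activity difference| over co-coupled receptors, per pair.

    ``vectors`` must be the masked (NaN for non-coupler) matrix; a pair
    with no co-coupled receptor stays NaN.
    """
    units = list(vectors.columns)
    out = pd.DataFrame(np.nan, index=units, columns=units)
    for i, a in enumerate(units):
        for j, b in enumerate(units):
            both = vectors[a].notna() & vectors[b].notna()
            if both.any():
                out.iloc[i, j] = abs(vectors.loc[both, a].mean()
                                     - vectors.loc[both, b].mean())
    return out


def correlation_tree(r: pd.DataFrame):
    """Average-linkage clustering of G proteins on correlation distance.

    Distance is 1 - r, computed from the complete Pearson matrix; leaf
    order is the deterministic scipy dendrogram order.  Returns
    ``(linkage_matrix, leaf_labels)``.
    """
    if r.isna().any().any():
        raise ValueError("correlation matrix has missing entries")
    dist = 1.0 - r.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(linkage)
    labels = [r.columns[i] for i in order]
    return linkage, labels


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node):
        if node.is_leaf():
            return labels[node.id], 0.0
        ls, lh = walk(node.left)
        rs, rh = walk(node.right)
        h = node.dist
        return f"({ls}:{h - lh:.6g},{rs}:{h - rh:.6g})", h

    s, _ = walk(tree)
    return s + ";"
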