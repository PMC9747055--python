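"""Genotype-masked risk-anatomy correlation and Ward dendrograms.

Z-scored canonical variates are multiplied by a one-hot genotype indicator
(non-carriers zeroed out, but retained in the correlation), then Spearman-
correlated with the z-scored risk factors, yielding one risk-by-variate
cross-association matrix per genotype (63 x 50 = 3,150 coefficients at the
reference dimensions).  Risk-factor rows are clustered with Ward's
minimum-variance method; dendrograms are cut at three levels of branching
from the root (<= 4 clusters).  Cluster models from different genotypes are
compared by Pearson-correlating their merge-distance sequences.

Spearman is computed as Pearson on mid-rank-transformed columns; the zeroed
non-carriers create massive ties, which mid-ranks handle — a faithful
reproduction of the masking design.  Ward linkage is delegated to
``scipy.cluster.hierarchy.linkage``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

__all__ = [
    "genotype_masked_spearman",
    "ward_cluster",
    "cut_tree_levels",
    "compare_cluster_models",
    "linkage_to_newick",
]


def genotype_masked_spearman(
    variates: pd.DataFrame,
    genotype_indicator: np.ndarray,
    risk_factors: pd.DataFrame,
    carriers_only: bool = False,
) -> pd.DataFrame:
    """Spearman matrix of risk factors against genotype-masked variates.

    ``variates`` is the z-scored (n x 2k) matrix of stacked HC/DN variate
    columns; carriers keep their values and non-carriers are set to zero
    before ranking (``carriers_only=True`` instead subsets to carriers).
    Returns the (n_risk x n_variates) Spearman matrix.
    """
    ind = np.asarray(genotype_indicator, dtype=float)
    if ind.sum() == 0:
        raise ValueError("genotype indicator selects no subjects")
    if len(ind) != len(variates) or len(variates) != len(risk_factors):
        raise ValueError("variates, indicator and risk factors must align")

    if carriers_only:
        mask = ind.astype(bool)
        V = variates.to_numpy(dtype=float)[mask]
        R = risk_factors.to_numpy(dtype=float)[mask]
    else:
        V = variates.to_numpy(dtype=float) * ind[:, None]
        R = risk_factors.to_numpy(dtype=float)

    Vr = rankdata(V, axis=0)  # mid-ranks for ties
    Rr = rankdata(R, axis=0)
    n = Vr.shape[0]
    Vs = (Vr - Vr.mean(axis=0)) / Vr.std(axis=0, ddof=0)
    Rs = (Rr - Rr.mean(axis=0)) / Rr.std(axis=0, ddof=0)
    corr = Rs.T @ Vs / n
    return pd.DataFrame(
        np.clip(corr, -1.0, 1.0),
        index=list(risk_factors.columns),
        columns=list(variates.columns),
    )


def ward_cluster(matrix: pd.DataFrame) -> np.ndarray:
    """Ward's minimum-variance linkage over the matrix rows.

    Returns the standard 4-column linkage array (left id, right id, merge
    distance, cluster size) with ``n_rows - 1`` merges; merge distances are
    monotone non-decreasing under Ward's criterion.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in cross-correlation matrix")
    return hierarchy.linkage(X, method="ward")


def cut_tree_levels(linkage: np.ndarray, levels: int = 3) -> np.ndarray:
    """Cluster labels after ``levels`` of branching from the final merge.

    Undoing the last ``levels`` merges yields at most ``levels + 1``
    clusters (fewer when the tree is unbalanced near the root); labels are
    1-based as in scipy's ``fcluster``.
    """
    n_leaves = linkage.shape[0] + 1
    return hierarchy.fcluster(linkage, t=min(levels + 1, n_leaves), criterion="maxclust")


def compare_cluster_models(tree_a: np.ndarray, tree_b: np.ndarray) -> float:
    """Pearson r between two trees' merge-distance sequences by merge step."""
    if tree_a.shape[0] != tree_b.shape[0]:
        raise ValueError("trees have different leaf counts")
    return float(np.corrcoef(tree_a[:, 2], tree_b[:, 2])[0, 1])


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a linkage array as a Newick string (branch lengths = heights)."""
    n = linkage.shape[0] + 1
    if len(leaf_names) != n:
        raise ValueError("leaf name count does not match linkage")
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: leaf_names[i] for i in range(n)}
    for step, (a, b, dist, _size) in enumerate(linkage):
        a, b = int(a), int(b)
        la = dist - heights[a]
        lb = dist - heights[b]
        nodes[n + step] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + step] = dist
    return nodes[2 * n - 2] + ";"
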