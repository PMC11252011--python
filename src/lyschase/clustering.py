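"""Longevity and abundance clustering.

Both schemes use agglomerative hierarchical clustering with Ward linkage
on Euclidean distances -- the criterion that minimizes within-cluster
variance -- and cut the tree at a fixed number of clusters: three
longevity groups (high/intermediate/low modelled heavy-label retention,
computed on ages >= 6 weeks) and six aging abundance trend groups on
per-protein z-scored DIA profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_samples

__all__ = [
    "longevity_cluster",
    "abundance_cluster",
    "zscore_rows",
    "linkage_to_newick",
]

LONGEVITY_LABELS = ("high", "intermediate", "low")
LONGEVITY_MIN_AGE = 42.0


def _ward_cut(matrix: np.ndarray, k: int):
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds number of proteins ({matrix.shape[0]})")
    link = hierarchy.linkage(matrix, method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return link, raw


def _silhouettes(matrix: np.ndarray, raw: np.ndarray) -> np.ndarray:
    if len(np.unique(raw)) < 2:
        return np.full(matrix.shape[0], np.nan)
    return silhouette_samples(matrix, raw)


def longevity_cluster(percent_heavy: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Cluster modelled %heavy trajectories into longevity groups.

    ``percent_heavy``: rows = proteins, columns = ages (days); columns at
    ages below 6 weeks are dropped before clustering.  Clusters are ranked
    by descending mean retention and labelled high/intermediate/low (for
    k = 3; otherwise rank_1..rank_k).  Ties (e.g. all-identical rows,
    where the cut is arbitrary) break by first protein index.
    """
    cols = [c for c in percent_heavy.columns if float(c) >= LONGEVITY_MIN_AGE]
    if not cols:
        raise ValueError("no columns at ages >= 42 days")
    X = percent_heavy[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("model-inferred matrix must be complete")
    link, raw = _ward_cut(X, k)
    means = {c: X[raw == c].mean() for c in np.unique(raw)}
    order = sorted(means, key=lambda c: (-means[c], c))
    if k == len(LONGEVITY_LABELS):
        name = {c: LONGEVITY_LABELS[i] for i, c in enumerate(order)}
    else:
        name = {c: f"rank_{i + 1}" for i, c in enumerate(order)}
    sil = _silhouettes(X, raw)
    return pd.DataFrame({
        "protein_id": percent_heavy.index,
        "scheme": "longevity",
        "label": [name[c] for c in raw],
        "silhouette": sil,
    })


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each row to mean 0 and scale to population s.d. 1.

    Constant rows cannot be scaled and are dropped with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 columns to z-score")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant rows before z-scoring")
    Z = (X[~constant] - mu[~constant]) / sd[~constant]
    return pd.DataFrame(Z, index=matrix.index[~constant], columns=matrix.columns)


def abundance_cluster(z_matrix: pd.DataFrame, k: int = 6) -> pd.DataFrame:
    """Cluster z-scored abundance profiles into ``k`` trend groups (labels 1..k).

    Labels are assigned deterministically: clusters are ordered by the
    mean z-score of their last column (descending; late-rising trends
    first), then by first protein index.
    """
    X = z_matrix.to_numpy(dtype=float)
    link, raw = _ward_cut(X, k)
    last = {c: X[raw == c][:, -1].mean() for c in np.unique(raw)}
    first_idx = {c: int(np.nonzero(raw == c)[0][0]) for c in np.unique(raw)}
    order = sorted(last, key=lambda c: (-last[c], first_idx[c]))
    name = {c: i + 1 for i, c in enumerate(order)}
    sil = _silhouettes(X, raw)
    return pd.DataFrame({
        "protein_id": z_matrix.index,
        "scheme": "abundance",
        "label": [name[c] for c in raw],
        "silhouette": sil,
    })


def ward_linkage(matrix) -> np.ndarray:
    """Expose the Ward dendrogram (scipy linkage matrix) for provenance."""
    return hierarchy.linkage(np.asarray(matrix, dtype=float), method="ward")


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)
    labels = list(labels)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
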