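"""Cell-population and SNV co-occurrence structure from the ternary matrix.

Dissimilarity between two cells is the Jaccard complement of their mutation
profiles over co-observed (both non-NA) sites; two cells with no mutation
among co-observed sites are identical (d = 0). Pairs with too few co-observed
sites are imputed at the mean of the supported entries and flagged. Cell
populations come from average-linkage agglomeration (k chosen by maximal
silhouette when automatic); the 2-D map is classical (Torgerson) MDS. SNV
clusters use the same machinery on the transposed matrix: the distance
between two SNVs is the Jaccard complement of their cell-presence sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "CellDistanceMatrix",
    "pairwise_cell_distance",
    "hierarchical_cluster",
    "classical_mds",
    "cluster_snvs",
]


@dataclass
class CellDistanceMatrix:
    d: pd.DataFrame          # symmetric, zero-diagonal, in [0, 1]
    support: pd.DataFrame    # co-observed site counts
    imputed: pd.DataFrame    # True where d was mean-imputed (low support)


def _jaccard_complement(values: np.ndarray, min_support: int
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = (~np.isnan(values)).astype(float)
    mut = np.nan_to_num(values) == 1.0
    mut = mut.astype(float)
    both = mut @ mut.T
    either = mut @ obs.T + obs @ mut.T - both
    support = obs @ obs.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(either > 0, 1.0 - both / np.maximum(either, 1e-300), 0.0)
    low = support < min_support
    np.fill_diagonal(low, False)
    defined = ~low
    np.fill_diagonal(defined, False)
    if low.any():
        fill = d[defined].mean() if defined.any() else 0.5
        d = np.where(low, fill, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0   # guard against float asymmetry
    return d, support, low


def pairwise_cell_distance(m, min_support: int = 10) -> CellDistanceMatrix:
    """Missing-data-aware Jaccard-complement distances between cells."""
    values = m.df.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    n_obs = (~np.isnan(values)).sum(axis=1)
    if (n_obs == 0).any():
        bad = list(m.df.index[n_obs == 0])
        raise ValueError(f"cells with no observed sites: {bad}")
    d, support, low = _jaccard_complement(values, min_support)
    idx = m.df.index
    return CellDistanceMatrix(
        d=pd.DataFrame(d, index=idx, columns=idx),
        support=pd.DataFrame(support.astype(int), index=idx, columns=idx),
        imputed=pd.DataFrame(low, index=idx, columns=idx),
    )


def _auto_k(d: np.ndarray, z: np.ndarray, k_max: int = 10) -> tuple[int, dict]:
    n = d.shape[0]
    scores = {}
    for k in range(2, min(k_max, n - 1) + 1):
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(d, labels, metric="precomputed"))
    if not scores:
        return 1, scores
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def hierarchical_cluster(dist: CellDistanceMatrix, k="auto"
                         ) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage agglomeration; silhouette-maximal k when automatic.

    Returns (labels, linkage). Labels are 1-based cluster ids, deterministic
    for a given distance matrix.
    """
    d = dist.d.to_numpy(dtype=float)
    n = d.shape[0]
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    if k == "auto":
        k, _ = _auto_k(d, z)
    else:
        k = int(k)
        if k > n:
            raise ValueError(f"k={k} exceeds number of cells {n}")
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=dist.d.index, name="cluster"), z


def tissue_composition(labels: pd.Series, tissues: pd.Series) -> pd.DataFrame:
    """Per-cluster tissue breakdown (counts), clusters in rows."""
    df = pd.DataFrame({"cluster": labels, "tissue": tissues.reindex(labels.index)})
    return df.groupby(["cluster", "tissue"]).size().unstack(fill_value=0)


def classical_mds(dist: CellDistanceMatrix | pd.DataFrame,
                  dims: int = 2) -> pd.DataFrame:
    """Torgerson MDS: eigendecomposition of the double-centred squared
    distance matrix. Signs are fixed by making the largest-magnitude loading
    of each axis positive, so the embedding is fully deterministic.
    """
    d = dist.d if isinstance(dist, CellDistanceMatrix) else dist
    index = d.index
    d = d.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(np.abs(evals[evals < 0]).sum())
    tot_mass = float(np.abs(evals).sum())
    if tot_mass > 0 and neg_mass / tot_mass > 0.20:
        warnings.warn("distances are far from Euclidean: negative eigenvalue "
                      f"mass is {100 * neg_mass / tot_mass:.1f}% of spectrum",
                      stacklevel=2)
    coords = np.zeros((n, dims))
    for a in range(min(dims, n)):
        lam = max(evals[a], 0.0)
        axis = evecs[:, a] * np.sqrt(lam)
        pivot = int(np.argmax(np.abs(axis)))
        if axis[pivot] < 0:
            axis = -axis
        coords[:, a] = axis
    return pd.DataFrame(coords, index=index,
                        columns=[f"dim{a + 1}" for a in range(dims)])


def cluster_snvs(m, k="auto", min_support: int = 10) -> pd.DataFrame:
    """Group SNVs by co-occurrence across cells.

    Distance between SNV columns is the Jaccard complement of their
    cell-presence sets (cells NA in either column excluded pairwise).
    Returns per-SNV cluster id plus the member-prevalence range (percent of
    cells) of its cluster.
    """
    if m.df.shape[1] < 2:
        raise ValueError("need at least 2 SNVs")
    values = m.df.to_numpy(dtype=float).T    # snvs x cells
    d, _, _ = _jaccard_complement(values, min_support)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    if k == "auto":
        k, _ = _auto_k(d, z)
    else:
        k = int(k)
    if k == 1:
        labels = np.ones(values.shape[0], dtype=int)
    else:
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    prevalence = 100.0 * (m.df == 1.0).sum(axis=0) / len(m.df)
    out = pd.DataFrame({
        "snv_key": m.df.columns,
        "snv_cluster": labels,
        "prevalence": prevalence.to_numpy(),
    })
    ranges = out.groupby("snv_cluster")["prevalence"].agg(["min", "max"])
    out = out.merge(ranges.rename(columns={"min": "cluster_prevalence_min",
                                           "max": "cluster_prevalence_max"}),
                    left_on="snv_cluster", right_index=True)
    return out.reset_index(drop=True)
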