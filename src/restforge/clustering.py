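"""Hierarchical clustering of GA-derived model populations.

A genetic algorithm returns a population of near-equivalent parameter
sets, not a unique optimum.  To quantify that calibration uncertainty the
final population is organized by agglomerative hierarchical clustering
(average linkage on Euclidean distances in log2 fold-change space), the
dendrogram is cut into the most dissimilar top-level clusters, and the
cluster centroids are simulated alongside the best-fit model: matching
emergent behavior across centroids indicates a reliable calibration.

The cophenetic correlation coefficient — the Pearson correlation between
original pairwise distances and the distances implied by the dendrogram —
summarizes how faithfully the tree represents the population geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

from .params import BOFCParams, PARAM_NAMES, make_base_params

__all__ = [
    "PopulationMatrix",
    "LinkageTree",
    "ClusterCut",
    "PopulationClustering",
    "normalize_population",
    "denormalize_population",
    "ahc_linkage",
    "cut_top",
    "percentile_constrain",
]


@dataclass
class PopulationMatrix:
    """Population in normalized (log2 fold-change vs base) coordinates."""

    values: np.ndarray  # (n, 28)
    base: BOFCParams
    row_index: np.ndarray  # indices into the originating population

    @property
    def n(self) -> int:
        return self.values.shape[0]


def normalize_population(matrix: np.ndarray, base: BOFCParams | None = None) -> PopulationMatrix:
    """log2 fold-change of each parameter against the base set.

    Distances on raw parameters would be dominated by the large time
    constants; the fold-change scale weighs a doubling of any parameter
    equally.  Columns whose base value is zero must be zero throughout
    (frozen parameters) and map to 0.
    """
    base = base or make_base_params()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"population must be (n, {len(PARAM_NAMES)})")
    if np.any(~np.isfinite(m)):
        raise ValueError("population contains non-finite values")
    b = base.to_vector()
    out = np.zeros_like(m)
    nz = b != 0.0
    if np.any(m[:, nz] <= 0.0):
        raise ValueError("non-positive parameter where base is positive")
    if np.any(m[:, ~nz] != 0.0):
        raise ValueError("nonzero value in a zero-base (frozen) column")
    out[:, nz] = np.log2(m[:, nz] / b[nz])
    return PopulationMatrix(values=out, base=base, row_index=np.arange(m.shape[0]))


def denormalize_population(pm: PopulationMatrix) -> np.ndarray:
    """Inverse of :func:`normalize_population`."""
    b = pm.base.to_vector()
    out = np.zeros_like(pm.values)
    nz = b != 0.0
    out[:, nz] = b[nz] * np.exp2(pm.values[:, nz])
    return out


@dataclass
class LinkageTree:
    """Agglomerative merge tree plus its cophenetic correlation."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    cophenetic: float | None  # None when all pairwise distances are 0
    method: str
    pm: PopulationMatrix = field(repr=False, default=None)


def ahc_linkage(pm: PopulationMatrix, method: str = "average") -> LinkageTree:
    """Average-linkage clustering on Euclidean distances in normalized space."""
    if pm.n < 2:
        raise ValueError("need at least two individuals")
    d = pdist(pm.values, metric="euclidean")
    z = linkage(d, method=method)
    if np.all(d == 0.0):
        coph = None  # degenerate: correlation undefined, tree still valid
    else:
        c, _ = cophenet(z, d)
        coph = float(c)
    return LinkageTree(merges=z, cophenetic=coph, method=method, pm=pm)


@dataclass
class ClusterCut:
    """Top-k cut of a linkage tree."""

    k: int
    labels: np.ndarray  # cluster id per row, 0..k-1 ordered by size desc
    sizes: np.ndarray  # descending
    centroids: list  # BOFCParams per cluster, same order as sizes


def cut_top(tree: LinkageTree, k: int) -> ClusterCut:
    """Partition into the ``k`` most dissimilar clusters.

    Cuts the dendrogram at the (k-1) highest merge heights (scipy
    ``maxclust``; ties broken deterministically by merge order).  Cluster
    ids are relabelled by descending size and centroids are the
    arithmetic means of members in normalized space, de-normalized to
    parameter sets.
    """
    n = tree.pm.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    raw = fcluster(tree.merges, t=k, criterion="maxclust")
    ids, counts = np.unique(raw, return_counts=True)
    order = np.argsort(counts, kind="stable")[::-1]
    labels = np.empty(n, dtype=int)
    centroids = []
    for new_id, oi in enumerate(order):
        members = raw == ids[oi]
        labels[members] = new_id
        mean_norm = tree.pm.values[members].mean(axis=0)
        sub = PopulationMatrix(
            values=mean_norm[None, :], base=tree.pm.base, row_index=np.array([0])
        )
        centroids.append(BOFCParams.from_vector(denormalize_population(sub)[0]))
    return ClusterCut(k=k, labels=labels, sizes=counts[order], centroids=centroids)


def percentile_constrain(pm: PopulationMatrix, p: float) -> PopulationMatrix:
    """Rows whose every parameter lies inside the central percentile band.

    ``p`` = 95 keeps rows with all 28 values within the [5th, 95th]
    percentile of that parameter's marginal distribution; controls the
    influence of extreme parameter values on the clustering.
    """
    if not 50.0 < p <= 100.0:
        raise ValueError("p must be in (50, 100]")
    if p == 100.0:
        return PopulationMatrix(
            values=pm.values.copy(), base=pm.base, row_index=pm.row_index.copy()
        )
    lo = np.percentile(pm.values, 100.0 - p, axis=0)
    hi = np.percentile(pm.values, p, axis=0)
    keep = np.all((pm.values >= lo) & (pm.values <= hi), axis=1)
    if not keep.any():
        raise ValueError(f"no rows inside the {p}th percentile band")
    return PopulationMatrix(
        values=pm.values[keep], base=pm.base, row_index=pm.row_index[keep]
    )


class PopulationClustering(ClusterMixin, BaseEstimator):
    """Sklearn-style wrapper: normalize, link, cut, and summarize.

    Parameters
    ----------
    k : int
        Number of top-level clusters for the reported cut (2 or 4 in the
        standard analysis).
    method : str
        Linkage method (average by default).
    percentile : float
        Optional per-parameter percentile constraint applied before
        clustering (100 = no constraint).
    """

    def __init__(self, k: int = 2, method: str = "average", percentile: float = 100.0):
        self.k = k
        self.method = method
        self.percentile = percentile

    def fit(self, X, y=None):
        pm = normalize_population(np.asarray(X, dtype=float))
        pm = percentile_constrain(pm, self.percentile)
        tree = ahc_linkage(pm, self.method)
        cut = cut_top(tree, self.k)
        self.tree_ = tree
        self.cophenetic_ = tree.cophenetic
        self.labels_ = cut.labels
        self.cluster_sizes_ = cut.sizes
        self.centroids_ = cut.centroids
        self.row_index_ = pm.row_index
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
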