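"""Unsupervised multi-cluster feature selection (MCFS).

MCFS scores each feature by how well it can reproduce the data's spectral
cluster structure without labels:

1. build a k-nearest-neighbor affinity graph with heat-kernel weights on
   the standardized feature rows;
2. solve the generalized eigenproblem ``L y = lambda D y`` of the graph
   Laplacian and keep the smallest non-trivial eigenvectors, one per
   putative cluster;
3. regress each eigenvector on the features with an L1-path
   (least-angle regression);
4. the MCFS score of feature j is the maximum absolute coefficient it
   attains across eigenvectors.

Features that separate the clusters earn large coefficients for some
eigenvector and therefore large scores; pure-noise features do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import Lars
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigurationError, FecgSqaError

__all__ = ["MCFSResult", "mcfs_scores", "select_top"]


@dataclass
class MCFSResult:
    """Per-feature MCFS scores and the induced ranking."""

    scores: pd.Series          # indexed by feature name, order preserved
    ranking: list              # feature names, descending score
    parameters: dict

    def __post_init__(self):
        if (self.scores < 0).any():
            raise ConfigurationError("MCFS scores must be non-negative")


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std


def mcfs_scores(X, n_clusters: int = 3, n_neighbors: int = 5) -> MCFSResult:
    """Score features by the multi-cluster feature-selection criterion.

    ``X`` is a feature matrix (DataFrame with named columns, or ndarray).
    Columns are standardized internally, so scores are invariant to
    affine column rescaling; rows may arrive in any order.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(values.shape[1])]
    n, d = values.shape
    if n < n_neighbors + 1:
        raise ConfigurationError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, got {n}")
    if not np.isfinite(values).all():
        raise ConfigurationError("feature matrix contains non-finite values")

    Z = _standardize(values)

    # heat-kernel kNN affinity graph
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(Z)
    dist, idx = nn.kneighbors(Z)
    sigma = np.median(pdist(Z)) if n <= 3000 else np.median(dist[:, 1:])
    if sigma == 0:
        sigma = 1.0
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = idx[:, 1:].ravel()
    weights = np.exp(-(dist[:, 1:].ravel() ** 2) / (2 * sigma ** 2))
    W[rows, cols] = weights
    W = np.maximum(W, W.T)

    degrees = W.sum(axis=1)
    if np.any(degrees == 0):
        n_comp, labels = connected_components(W > 0, directed=False)
        raise FecgSqaError(
            f"degenerate affinity graph: isolated vertices; "
            f"{n_comp} components with sizes {np.bincount(labels).tolist()}")

    D = np.diag(degrees)
    L = D - W
    # smallest eigenpairs of L y = lambda D y; skip the trivial constant one
    eigvals, eigvecs = linalg.eigh(L, D, subset_by_index=(0, n_clusters))
    Y = eigvecs[:, 1:n_clusters + 1]

    scores = np.zeros(d)
    for k in range(Y.shape[1]):
        reg = Lars(n_nonzero_coefs=d, fit_intercept=True)
        reg.fit(Z, Y[:, k])
        scores = np.maximum(scores, np.abs(reg.coef_))

    series = pd.Series(scores, index=names)
    order = np.lexsort((np.arange(d), -scores))
    ranking = [names[i] for i in order]
    return MCFSResult(
        scores=series, ranking=ranking,
        parameters={"n_clusters": n_clusters, "n_neighbors": n_neighbors,
                    "bandwidth": float(sigma), "sparsity": "densest (all coefficients)"})


def select_top(result: MCFSResult, k: int = 5) -> list:
    """First ``k`` feature names of the MCFS ranking (ties pre-resolved)."""
    if not (1 <= k <= len(result.ranking)):
        raise ConfigurationError(
            f"k must lie in [1, {len(result.ranking)}], got {k}")
    return result.ranking[:k]
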