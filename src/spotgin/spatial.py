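"""Spatial weights, Moran's I autocorrelation and the spatial
cross-correlation index (SCI).

Weights are binary and unnormalized by default (the statistics below use
raw w_ij); six nearest neighbors mirror the hexagonal Visium packing.

    I   = (N / W) * sum_ij w_ij (X_i - Xbar)(X_j - Xbar) / sum_i (X_i - Xbar)^2
    SCI = N / (2 sum_ij W_ij)
          * sum_ij W_ij (x_i - xbar)(y_j - ybar)
          / ( sqrt(sum_i (x_i - xbar)^2) * sqrt(sum_j (y_j - ybar)^2) )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors


@dataclass
class SpatialWeights:
    """Symmetric non-negative spot x spot weights with zero diagonal."""

    w: sp.csr_matrix

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.w)
        if (w != w.T).nnz:
            raise ValueError("weights must be symmetric")
        if w.diagonal().any():
            raise ValueError("weights must have zero diagonal")
        if w.data.size and w.data.min() < 0:
            raise ValueError("weights must be non-negative")
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def total(self) -> float:
        """W, the sum of all spatial weights."""
        return float(self.w.sum())

    def row_standardized(self) -> "SpatialWeights":
        rowsum = np.asarray(self.w.sum(axis=1)).ravel()
        inv = np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1e-300), 0.0)
        return SpatialWeights(sp.diags(inv) @ self.w)


def build_weights(coords: np.ndarray, rule: str = "knn", k: int = 6,
                  threshold_factor: float = 1.05) -> SpatialWeights:
    """Binary spatial weights from coordinates.

    ``rule='knn'``: k nearest neighbors, symmetrized by union (default
    k=6, the hex neighborhood). ``rule='threshold'``: pairs within
    ``threshold_factor`` x the smallest nonzero pairwise distance.
    Coincident coordinates are rejected.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two spots")
    dist = pdist(coords)
    if (dist == 0).any():
        raise ValueError("coincident duplicate coordinates")
    if rule == "knn":
        k_eff = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
        graph = nn.kneighbors_graph(coords, mode="connectivity")
        graph.setdiag(0)
        graph.eliminate_zeros()
        w = graph.maximum(graph.T)
    elif rule == "threshold":
        thr = threshold_factor * dist.min()
        dense = squareform(dist)
        mask = (dense <= thr) & (dense > 0)
        w = sp.csr_matrix(mask.astype(float))
    else:
        raise ValueError("rule must be 'knn' or 'threshold'")
    return SpatialWeights(w)


def morans_i(x: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I; positive = clustering, negative = dispersion."""
    x = np.asarray(x, float)
    if len(x) != weights.n:
        raise ValueError("value vector does not match weights")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance")
    cross = float(z @ (weights.w @ z))
    return len(x) / weights.total * cross / denom


def morans_i_permutation(x: np.ndarray, weights: SpatialWeights,
                         n_perm: int = 999, seed: int = 0) -> dict:
    """Permutation null for Moran's I (two-sided pseudo p-value)."""
    rng = np.random.default_rng(seed)
    observed = morans_i(x, weights)
    x = np.asarray(x, float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = morans_i(rng.permutation(x), weights)
    p = (np.sum(np.abs(null - null.mean()) >= abs(observed - null.mean())) + 1) \
        / (n_perm + 1)
    return {"i": observed, "p": float(p), "null_mean": float(null.mean()),
            "null_sd": float(null.std())}


def sci(x: np.ndarray, y: np.ndarray, weights: SpatialWeights) -> float:
    """Spatial cross-correlation index between two per-spot features."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != weights.n or len(y) != weights.n:
        raise ValueError("feature vectors do not match weights")
    zx = x - x.mean()
    zy = y - y.mean()
    sx = np.sqrt(zx @ zx)
    sy = np.sqrt(zy @ zy)
    if sx == 0 or sy == 0:
        raise ValueError("constant feature")
    cross = float(zx @ (weights.w @ zy))
    return weights.n / (2.0 * weights.total) * cross / (sx * sy)


def sci_matrix(features: np.ndarray, weights: SpatialWeights,
               names=None) -> "pd.DataFrame":
    """Pairwise SCI for feature columns; constant features yield NaN rows."""
    import pandas as pd

    F = np.asarray(features, float)
    n_feat = F.shape[1]
    names = list(names) if names is not None else list(range(n_feat))
    out = np.full((n_feat, n_feat), np.nan)
    for a in range(n_feat):
        for b in range(n_feat):
            try:
                out[a, b] = sci(F[:, a], F[:, b], weights)
            except ValueError:
                pass
    return pd.DataFrame(out, index=names, columns=names)
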