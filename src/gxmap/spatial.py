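"""Spatial machinery: k-NN weight graphs, Moran's I, and Moran eigenvector maps.

The regional association analysis treats every donor's set of tissue samples
as a point pattern in (cortical) space.  Spatial structure enters in three
places, all served by this module:

* a symmetrised k-nearest-neighbour graph over inter-sample distances,
  row-standardised into a spatial weight matrix ``W``;
* Moran's I with the randomisation (permutation-moment) null, used to test
  regression residuals for spatial autocorrelation;
* the Moran eigenvector map (MEM) basis — eigenvectors of the doubly-centered
  symmetrised weight matrix — whose leading vectors encode the smoothest
  spatial patterns supported by the graph and serve as regression covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "SpatialGraph",
    "MoranResult",
    "EigenvectorBasis",
    "build_knn_graph",
    "moran_i",
    "compute_mem",
]


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input (e.g. constant x)."""


@dataclass
class SpatialGraph:
    """Row-standardised spatial weights from a symmetrised k-NN relation.

    Attributes
    ----------
    n : int
        Number of nodes (samples).
    adjacency : scipy.sparse.csr_matrix
        Binary, symmetric (union rule), zero-diagonal adjacency.
    weights : scipy.sparse.csr_matrix
        Row-standardised weights: each row with at least one neighbour sums to 1.
    k : int
        The k used to build the nearest-neighbour relation.
    """

    n: int
    adjacency: sp.csr_matrix
    weights: sp.csr_matrix
    k: int
    _moments: tuple[float, float, float] | None = field(default=None, repr=False)

    def moran_moments(self) -> tuple[float, float, float]:
        """Return (S0, S1, S2), the weight-matrix sums entering Moran's variance.

        Cached: the graph is reused for thousands of residual tests per donor.
        """
        if self._moments is None:
            w = self.weights
            s0 = float(w.sum())
            wt = w.T.tocsr()
            s1 = 0.5 * float((w + wt).power(2).sum())
            row = np.asarray(w.sum(axis=1)).ravel()
            col = np.asarray(w.sum(axis=0)).ravel()
            s2 = float(((row + col) ** 2).sum())
            self._moments = (s0, s1, s2)
        return self._moments


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its randomisation-null moments and one-sided test."""

    I: float
    expected: float
    variance: float
    z: float
    p: float


@dataclass(frozen=True)
class EigenvectorBasis:
    """Moran eigenvector map basis: orthonormal, centered spatial patterns.

    ``vectors`` is n x m with columns sorted by eigenvalue descending, so the
    leading columns carry positive spatial autocorrelation (smooth patterns)
    and trailing ones negative.  Eigenvalues within 1e-12 of zero (relative to
    the largest magnitude) are dropped — this removes the trivial constant
    direction introduced by centering.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def build_knn_graph(dist: np.ndarray, k: int = 10) -> SpatialGraph:
    """Build the symmetrised k-NN spatial weight graph from a distance matrix.

    Node j is a neighbour of i iff j is among i's k nearest *or* i is among
    j's k nearest (union symmetrisation).  The binary adjacency is then
    row-standardised.  Ties at the k-th distance are broken by smallest index.

    Parameters
    ----------
    dist : (n, n) array
        Symmetric distances with zero diagonal (any metric; typically a
        geodesic surrogate along the cortical sheet).
    k : int
        Number of nearest neighbours per node before symmetrisation.

    Raises
    ------
    ValueError
        If the matrix is not square/symmetric/zero-diagonal or n <= k.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    n = dist.shape[0]
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n <= k:
        raise ValueError(f"need more than k={k} nodes, got n={n}")

    # Stable argsort breaks ties at the k-th distance by smallest index.
    order = np.argsort(dist, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=int)
    for i in range(n):
        nn = order[i][order[i] != i][:k]
        cols[i * k : (i + 1) * k] = nn
    adj = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    adj = ((adj + adj.T) > 0).astype(float)
    adj.setdiag(0.0)
    adj.eliminate_zeros()

    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    weights = sp.diags(inv) @ adj
    return SpatialGraph(n=n, adjacency=adj.tocsr(), weights=weights.tocsr(), k=k)


def moran_i(x: np.ndarray, g: SpatialGraph) -> MoranResult:
    """Moran's I of ``x`` on graph ``g``, tested one-sided (greater).

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    The null moments use the randomisation (permutation) assumption, under
    which E[I] = -1/(n-1) and the variance involves the sample kurtosis; the
    p-value is the upper normal tail — positive autocorrelation being the
    alerted direction when testing regression residuals.

    Raises
    ------
    DegenerateInputError
        If ``x`` is constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = g.n
    if x.size != n:
        raise ValueError(f"x has length {x.size}, graph has {n} nodes")
    z = x - x.mean()
    ss = float(z @ z)
    if ss <= 0.0:
        raise DegenerateInputError("Moran's I is undefined for a constant vector")

    s0, s1, s2 = g.moran_moments()
    I = (n / s0) * float(z @ (g.weights @ z)) / ss
    ei = -1.0 / (n - 1)
    b2 = n * float((z**4).sum()) / ss**2
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var = num / den - ei * ei
    zscore = (I - ei) / np.sqrt(var)
    p = float(stats.norm.sf(zscore))
    # Clip away exact 0/1 so downstream log/quantile transforms stay finite.
    p = float(np.clip(p, np.finfo(float).tiny, 1.0 - 1e-16))
    return MoranResult(I=float(I), expected=ei, variance=float(var), z=float(zscore), p=p)


def compute_mem(g: SpatialGraph, drop_tol: float = 1e-12) -> EigenvectorBasis:
    """Moran eigenvector maps of the graph's weight structure.

    Eigendecomposition of C @ Wsym @ C where C = I - 11'/n is the centering
    projector and Wsym = (W + W') / 2 symmetrises the row-standardised
    weights.  Columns are sorted by eigenvalue descending, so leading vectors
    maximise Moran's I on the graph.  Eigenvalues with magnitude below
    ``drop_tol`` times the largest magnitude are dropped (the centered-out
    constant direction).

    Raises
    ------
    ValueError
        If the graph has fewer than 3 nodes.
    """
    n = g.n
    if n < 3:
        raise ValueError("need at least 3 nodes for an eigenvector basis")
    w = g.weights.toarray()
    wsym = 0.5 * (w + w.T)
    wsym -= wsym.mean(axis=0, keepdims=True)
    wsym -= wsym.mean(axis=1, keepdims=True)
    # double-centering of a symmetric matrix keeps it symmetric up to rounding
    wsym = 0.5 * (wsym + wsym.T)
    evals, evecs = np.linalg.eigh(wsym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    keep = np.abs(evals) > drop_tol * np.abs(evals).max()
    return EigenvectorBasis(vectors=evecs[:, keep], eigenvalues=evals[keep])
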