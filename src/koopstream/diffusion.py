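"""Diffusion maps over delay coordinates.

A Gaussian kernel ``exp(-||xi - xj||^2 / eps^2)`` is evaluated on a
kNN-sparsified graph, symmetrized by the union rule, and row-normalized
into a Markov matrix P.  The leading eigenvectors of P (computed through
the symmetric conjugate ``D^{1/2} P D^{-1/2}`` for numerical stability)
approximate a Fourier-like basis adapted to the geometry of the embedded
trajectory and serve as the eDMD dictionary candidates.

The kernel exponent divides the squared distance by eps**2 (much of the
diffusion-maps literature divides by an un-squared bandwidth); set
``squared_bandwidth=False`` to switch conventions.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from sklearn.neighbors import NearestNeighbors

from .datatypes import DelayMatrix, DiffusionBasis, KoopstreamError

__all__ = ["select_epsilon", "knn_distances", "build_markov_matrix",
           "diffusion_eigendecomposition", "diffusion_basis"]


def _as_array(dm) -> np.ndarray:
    return dm.values if isinstance(dm, DelayMatrix) else np.asarray(dm, float)


def knn_distances(points: np.ndarray, k: int, exclude_window: int = 0):
    """Distances/indices of the k nearest neighbors (self excluded).

    ``exclude_window`` applies a Theiler window: rows whose *index*
    differs by at most this many samples are excluded from each other's
    neighborhoods.  Delay-coordinate rows within one delay span share
    almost all of their entries, so without the exclusion the graph is
    dominated by a temporal chain rather than by state-space recurrences.
    """
    n = len(points)
    if exclude_window <= 0:
        nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(points)
        dist, idx = nn.kneighbors(points)
        return dist[:, 1:], idx[:, 1:]
    k_query = min(k + 2 * exclude_window + 1, n)
    if k_query - 2 * exclude_window - 1 < k:
        raise KoopstreamError(
            "not enough points for the requested kNN with Theiler window")
    nn = NearestNeighbors(n_neighbors=k_query).fit(points)
    dist, idx = nn.kneighbors(points)
    keep_d = np.empty((n, k))
    keep_i = np.empty((n, k), dtype=int)
    rows = np.arange(n)
    mask = np.abs(idx - rows[:, None]) > exclude_window
    for i in range(n):
        sel = np.flatnonzero(mask[i])[:k]
        if len(sel) < k:
            raise KoopstreamError(
                f"point {i}: fewer than {k} neighbors outside the "
                "Theiler window")
        keep_d[i] = dist[i, sel]
        keep_i[i] = idx[i, sel]
    return keep_d, keep_i


def select_epsilon(dm, kmin: int = 12,
                   knn_dist: np.ndarray | None = None) -> float:
    """Bandwidth: mean over points of the mean distance to their ``kmin``
    nearest neighbors (Euclidean, self excluded).

    ``knn_dist`` may supply precomputed sorted neighbor distances with at
    least ``kmin`` columns to avoid a second kNN query.
    """
    x = _as_array(dm)
    if knn_dist is None:
        if x.shape[0] < kmin + 1:
            raise KoopstreamError("need at least kmin+1 points")
        knn_dist, _ = knn_distances(x, kmin)
    eps = float(np.mean(knn_dist[:, :kmin]))
    if eps <= 0:
        raise KoopstreamError("epsilon is zero: data points are duplicates")
    return eps


def build_markov_matrix(dm, epsilon: float, knn: int = 192,
                        squared_bandwidth: bool = True,
                        precomputed: tuple | None = None,
                        return_degrees: bool = False):
    """Row-stochastic kernel matrix on the union-symmetrized kNN graph.

    ``precomputed`` may carry (distances, indices) from a previous
    ``knn_distances`` call with at least ``knn`` columns.  With
    ``return_degrees=True`` the kernel row sums (the stationary measure of
    P, up to scale) are returned alongside P.
    """
    x = _as_array(dm)
    n = x.shape[0]
    if epsilon <= 0:
        raise KoopstreamError("epsilon must be positive")
    if knn >= n:
        raise KoopstreamError("knn must be smaller than the number of points")
    if precomputed is not None:
        dist, idx = precomputed
        dist, idx = dist[:, :knn], idx[:, :knn]
    else:
        dist, idx = knn_distances(x, knn)

    denom = epsilon ** 2 if squared_bandwidth else epsilon
    vals = np.exp(-(dist ** 2) / denom)
    rows = np.repeat(np.arange(n), knn)
    K = sp.csr_matrix((vals.ravel(), (rows, idx.ravel())), shape=(n, n))
    # union symmetrization: keep an edge if it is in either direction
    K = K.maximum(K.T)
    K.setdiag(1.0)  # kernel at zero distance

    if (np.asarray(K.sum(axis=1)).ravel() <= 1.0).any():
        raise KoopstreamError("isolated point in the kNN graph")
    n_comp, _ = csgraph.connected_components(K, directed=False)
    if n_comp > 1:
        warnings.warn(f"kNN graph has {n_comp} connected components",
                      RuntimeWarning, stacklevel=2)

    deg = np.asarray(K.sum(axis=1)).ravel()
    P = (sp.diags(1.0 / deg) @ K).tocsr()
    if return_degrees:
        return P, deg
    return P


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def diffusion_eigendecomposition(P: sp.spmatrix, n_eigs: int,
                                 degrees: np.ndarray | None = None,
                                 **meta) -> DiffusionBasis:
    """Leading eigenpairs of the Markov matrix P.

    Solved through the symmetric conjugate ``S = D^{1/2} P D^{-1/2}`` (all
    eigenvalues real, |lambda| <= 1); eigenvectors are mapped back to the
    right-eigenvector (Markov) convention, unit-normalized, sorted by
    descending eigenvalue, and sign-fixed.  ``degrees`` may pass the kernel
    row sums from :func:`build_markov_matrix`; otherwise the stationary
    distribution is recovered from P itself.
    """
    P = sp.csr_matrix(P)
    n = P.shape[0]
    if n_eigs < 1 or n_eigs > n:
        raise KoopstreamError("n_eigs out of range")
    pi = (np.asarray(degrees, float) if degrees is not None
          else _stationary_degrees(P))
    pi = pi / pi.sum()
    rt = np.sqrt(pi)
    S = sp.diags(rt) @ P @ sp.diags(1.0 / rt)
    S = (S + S.T) / 2  # clean round-off asymmetry
    if n_eigs >= n - 1 or n <= 400:
        vals, vecs = np.linalg.eigh(S.toarray())
        order = np.argsort(vals)[::-1][:n_eigs]
        vals, vecs = vals[order], vecs[:, order]
    else:
        try:
            v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic start vector
            vals, vecs = spla.eigsh(S, k=n_eigs, which="LA", v0=v0)
        except spla.ArpackNoConvergence as err:  # pragma: no cover
            raise KoopstreamError(
                f"eigensolver failed to converge: {err}") from err
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    psi = vecs / rt[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    psi = _fix_signs(psi)
    return DiffusionBasis(eigvals=vals, eigvecs=psi, **meta)


def _stationary_degrees(P: sp.csr_matrix) -> np.ndarray:
    """Degrees d_i (up to scale) of the symmetric kernel behind P.

    For P = D^-1 K with symmetric K, pi = d / sum(d) is stationary and
    satisfies pi_i P_ij = pi_j P_ji.  Solve via the dominant left
    eigenvector of P.
    """
    n = P.shape[0]
    if n <= 400:
        vals, vecs = np.linalg.eig(P.toarray().T)
        i = np.argmax(vals.real)
        pi = np.abs(vecs[:, i].real)
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = spla.eigs(P.T, k=1, which="LR", v0=v0)
        pi = np.abs(vecs[:, 0].real)
    pi = np.maximum(pi, 1e-300)
    return pi / pi.sum()


def diffusion_basis(dm: DelayMatrix, kmin: int = 12, knn: int = 192,
                    n_eigs: int = 150,
                    squared_bandwidth: bool = True,
                    theiler: int | None = None) -> DiffusionBasis:
    """End-to-end: bandwidth, Markov matrix, eigendecomposition.

    The kNN search is performed once with ``max(kmin, knn)`` neighbors and
    reused for both the bandwidth estimate and the kernel graph.
    ``theiler`` is the temporal exclusion window in samples (defaults to
    the delay span ``s``, the scale over which delay rows overlap).
    """
    k = max(kmin, knn)
    if theiler is None:
        theiler = dm.s
    dist, idx = knn_distances(dm.values, k, exclude_window=theiler)
    eps = select_epsilon(dm, kmin, knn_dist=dist)
    P, deg = build_markov_matrix(dm, eps, knn, squared_bandwidth,
                                 precomputed=(dist, idx),
                                 return_degrees=True)
    n_eigs = min(n_eigs, P.shape[0])
    return diffusion_eigendecomposition(
        P, n_eigs, degrees=deg, epsilon=eps, kmin=kmin, knn=knn, dt=dm.dt,
        start_index=dm.start_index, t0=dm.t0)
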