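"""Voxel adjacency graph, edge weights and the normalized Laplacian.

Vertices are the valid voxels; edges connect voxels whose grid
coordinates are at Euclidean distance <= 1, i.e. face neighbours
(4-neighbourhood in 2-D, 6-neighbourhood in 3-D). Edge weights are
similarities in (0, 1]:

* predefined metric: ``w_ij = exp(-dist(D_i, D_j)^2 / sigma^2)`` with a
  classical tensor metric and Gaussian bandwidth ``sigma`` (median edge
  distance by default);
* learned kernel:    ``w_ij = exp(-d_ij^T M d_ij)`` with the 4-component
  distance vector ``d_ij`` and a symmetric PSD matrix ``M`` (any global
  bandwidth is absorbed into ``M``).

The normalized Laplacian ``L = I - Dg^{-1/2} W Dg^{-1/2}`` (``Dg`` the
diagonal degree matrix of row sums) drives label propagation: its
quadratic form penalises label differences across strongly weighted
edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .distances import TENSOR_METRICS, distance_vectors
from .tensorfield import TensorField, compute_features, eigendecompose

__all__ = [
    "VoxelGraph", "build_adjacency", "weights_predefined",
    "weights_learned", "normalized_laplacian", "build_graph",
    "edge_distances_predefined", "export_edge_list",
]

_PSD_TOL = 1e-10


def build_adjacency(valid_mask: np.ndarray):
    """Enumerate face-adjacent valid voxel pairs.

    Returns
    -------
    edges : (E, 2) int array of node indices, each row i < j
    node_coords : (n, ndim) int array, node index -> grid coordinate
    node_index : grid-shaped int array, coordinate -> node index (-1 off-graph)
    """
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not np.any(valid_mask):
        raise ValueError("no valid voxels: cannot build a graph")
    node_index = -np.ones(valid_mask.shape, dtype=np.int64)
    node_coords = np.argwhere(valid_mask)
    node_index[valid_mask] = np.arange(len(node_coords))

    edges = []
    ndim = valid_mask.ndim
    for ax in range(ndim):
        sl_a = [slice(None)] * ndim
        sl_b = [slice(None)] * ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a = node_index[tuple(sl_a)]
        b = node_index[tuple(sl_b)]
        ok = (a >= 0) & (b >= 0)
        edges.append(np.column_stack([a[ok], b[ok]]))
    edges = np.concatenate(edges, axis=0)
    edges = np.sort(edges, axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order], node_coords, node_index


def edge_distances_predefined(edges, field: TensorField, node_coords,
                              metric: str = "euclidean") -> np.ndarray:
    """Classical tensor distances along each edge."""
    if metric not in TENSOR_METRICS:
        raise ValueError(f"unknown metric {metric!r}; "
                         f"choose from {sorted(TENSOR_METRICS)}")
    ti = field.tensors[tuple(node_coords[edges[:, 0]].T)]
    tj = field.tensors[tuple(node_coords[edges[:, 1]].T)]
    if metric == "euclidean":
        diff = ti - tj
        return np.sqrt(np.sum(diff * diff, axis=(-1, -2)))
    fn = TENSOR_METRICS[metric]
    return np.array([fn(a, b) for a, b in zip(ti, tj)])


def _weights_to_sparse(edges, w, n) -> sp.csr_matrix:
    i, j = edges[:, 0], edges[:, 1]
    W = sp.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
    return W.tocsr()


def weights_predefined(edges, field: TensorField, node_coords,
                       metric: str = "euclidean",
                       sigma: float | None = None) -> sp.csr_matrix:
    """Gaussian-kernel weight matrix under a classical tensor metric.

    ``w_ij = exp(-dist^2 / sigma^2)``. With ``sigma=None`` the median of
    the edge distances is used (median heuristic); ``sigma`` must be
    positive.
    """
    dist = edge_distances_predefined(edges, field, node_coords, metric)
    if sigma is None:
        # median heuristic over the informative edges: distances that are
        # zero (or numerically negligible next to the largest) carry no
        # scale information and would collapse the bandwidth
        pos = dist[dist > 1e-9 * dist.max()] if dist.max() > 0 else dist[:0]
        sigma = float(np.median(pos)) if pos.size else 1.0
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    w = np.exp(-(dist / sigma) ** 2)
    return _weights_to_sparse(edges, w, len(node_coords))


def weights_learned(edges, edge_dvecs: np.ndarray, M: np.ndarray,
                    n: int | None = None) -> sp.csr_matrix:
    """Mahalanobis-kernel weight matrix ``w_ij = exp(-d_ij^T M d_ij)``.

    ``M`` must be symmetric PSD (up to 1e-10); the quadratic form is
    clipped at zero to absorb roundoff at the PSD boundary.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"M must be 4x4, got {M.shape}")
    if np.abs(M - M.T).max() > 1e-12 * max(np.abs(M).max(), 1.0):
        raise ValueError("M must be symmetric")
    if np.linalg.eigvalsh(M)[0] < -_PSD_TOL:
        raise ValueError("M must be positive semi-definite")
    q = np.einsum("ek,kl,el->e", edge_dvecs, M, edge_dvecs)
    w = np.exp(-np.clip(q, 0.0, None))
    if n is None:
        n = int(edges.max()) + 1 if edges.size else 0
    return _weights_to_sparse(edges, w, n)


def normalized_laplacian(W: sp.spmatrix) -> sp.csr_matrix:
    """``L = I - Dg^{-1/2} W Dg^{-1/2}`` for a symmetric weight matrix.

    Raises if any vertex has zero degree (isolated voxels must be pruned
    before building the Laplacian).
    """
    W = W.tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        k = int(np.argmax(deg <= 0))
        raise ValueError(f"vertex {k} is isolated (zero degree)")
    dinv = sp.diags(1.0 / np.sqrt(deg))
    L = sp.eye(W.shape[0], format="csr") - dinv @ W @ dinv
    return L.tocsr()


@dataclass
class VoxelGraph:
    """Adjacency structure plus per-edge distance vectors for one field.

    ``edges`` holds each undirected edge once (i < j). ``W``/``L`` are
    built on demand by :func:`weights_predefined` / :func:`weights_learned`
    and :func:`normalized_laplacian`.
    """

    n: int
    edges: np.ndarray
    node_coords: np.ndarray
    node_index: np.ndarray
    edge_dvecs: np.ndarray
    features: object  # VoxelFeatures
    field: TensorField

    def labels_to_nodes(self, y_grid: np.ndarray) -> np.ndarray:
        """Flatten a grid of {+1,-1,0} constraints onto graph nodes."""
        return np.asarray(y_grid)[tuple(self.node_coords.T)]

    def nodes_to_grid(self, values: np.ndarray, fill=0):
        """Scatter per-node values back onto the grid."""
        out = np.full(self.node_index.shape, fill,
                      dtype=np.asarray(values).dtype)
        out[tuple(self.node_coords.T)] = values
        return out


def build_graph(field: TensorField) -> VoxelGraph:
    """Eigen-decompose, featurise and wire up the voxel graph of a field."""
    eig = eigendecompose(field)
    feat = compute_features(eig)
    edges, node_coords, node_index = build_adjacency(feat.valid_mask)
    dvecs = distance_vectors(feat, edges, node_coords)
    return VoxelGraph(
        n=len(node_coords), edges=edges, node_coords=node_coords,
        node_index=node_index, edge_dvecs=dvecs, features=feat, field=field,
    )


def export_edge_list(graph: VoxelGraph, W: sp.spmatrix, path):
    """Write the weighted edge list as text lines ``i j w`` (debug aid)."""
    W = W.tocsr()
    with open(path, "w") as fh:
        for i, j in graph.edges:
            fh.write(f"{i} {j} {W[i, j]:.12g}\n")
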