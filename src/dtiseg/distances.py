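"""Pairwise voxel distances: the 4-component distance vector and
classical tensor metrics.

The discriminative distance vector between two voxels concatenates three
geometry components — absolute differences of the normalised MD, FA and
VR features — with one orientation component, the minimum rotation angle
between the principal axes normalised so that orthogonal axes are at
distance 1. Principal eigenvectors carry an arbitrary sign, so the angle
is computed from ``|e_i . e_j|``: antiparallel vectors are the same axis
and have distance 0.

The three classical whole-tensor metrics (Euclidean, J-divergence,
geodesic) serve as baselines; each maps a pair of SPD tensors to a single
nonnegative scalar with no separate notion of geometry vs orientation.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = [
    "geometry_distance", "orientation_distance", "original_distance",
    "distance_vectors", "euclidean_metric", "jdivergence_metric",
    "geodesic_metric",
]


def geometry_distance(f_i: np.ndarray, f_j: np.ndarray) -> np.ndarray:
    """Component-wise |difference| of two normalised (MD, FA, VR) triples."""
    return np.abs(np.asarray(f_i, float) - np.asarray(f_j, float))


def orientation_distance(e_i: np.ndarray, e_j: np.ndarray) -> float:
    """Normalised minimum rotation angle between two principal axes.

    ``arccos(|e_i . e_j|) / (pi/2)``: 0 for collinear axes (either sign),
    1 for orthogonal ones. Inputs must be unit vectors.
    """
    e_i = np.asarray(e_i, float)
    e_j = np.asarray(e_j, float)
    ni, nj = np.linalg.norm(e_i), np.linalg.norm(e_j)
    if ni < 1e-12 or nj < 1e-12:
        raise ValueError("orientation_distance requires nonzero axis vectors")
    c = abs(float(e_i @ e_j) / (ni * nj))
    return float(np.arccos(min(c, 1.0)) / (np.pi / 2.0))


def original_distance(feat, i, j) -> np.ndarray:
    """The 4-vector (d_MD, d_FA, d_VR, d_orient) between voxels i and j.

    ``feat`` is a :class:`~dtiseg.tensorfield.VoxelFeatures`; ``i`` and
    ``j`` index its grid. Both voxels must be valid.
    """
    i, j = tuple(np.atleast_1d(i)), tuple(np.atleast_1d(j))
    if not (feat.valid_mask[i] and feat.valid_mask[j]):
        raise ValueError(f"voxel {i} or {j} is not valid")
    g = geometry_distance(feat.normalized()[i], feat.normalized()[j])
    o = orientation_distance(feat.principal_axis[i], feat.principal_axis[j])
    return np.concatenate([np.ravel(g), [o]])


def distance_vectors(feat, edges: np.ndarray, node_coords: np.ndarray) -> np.ndarray:
    """Vectorised distance vectors for a set of graph edges.

    Parameters
    ----------
    feat : VoxelFeatures
    edges : (E, 2) int array of node indices
    node_coords : (n, ndim) int array mapping node index -> grid coordinate

    Returns
    -------
    (E, 4) array of distance vectors, all components in [0, 1].
    """
    ci = tuple(node_coords[edges[:, 0]].T)
    cj = tuple(node_coords[edges[:, 1]].T)
    nf = feat.normalized()
    g = np.abs(nf[ci] - nf[cj])                     # (E, 3)
    ei = feat.principal_axis[ci]
    ej = feat.principal_axis[cj]
    dot = np.abs(np.einsum("ek,ek->e", ei, ej))
    o = np.arccos(np.clip(dot, 0.0, 1.0)) / (np.pi / 2.0)
    return np.column_stack([g, o])


# ---------------------------------------------------------------------------
# classical whole-tensor metrics

def _check_spd(D, name):
    w = np.linalg.eigvalsh(D)
    if w[0] <= 0.0:
        raise ValueError(f"{name} must be SPD (min eigenvalue {w[0]:.3e})")


def euclidean_metric(D1: np.ndarray, D2: np.ndarray) -> float:
    """Frobenius norm of the tensor difference, sqrt(trace((D1-D2)^2))."""
    diff = np.asarray(D1, float) - np.asarray(D2, float)
    return float(np.sqrt(np.sum(diff * diff)))


def jdivergence_metric(D1: np.ndarray, D2: np.ndarray) -> float:
    """Symmetrised Kullback-Leibler (J-divergence) distance.

    ``0.5 * sqrt(trace(D1^-1 D2 + D2^-1 D1) - 6)`` — the distance between
    the zero-mean Gaussians with covariances D1 and D2. Both tensors must
    be SPD.
    """
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    _check_spd(D1, "D1")
    _check_spd(D2, "D2")
    tr = np.trace(np.linalg.solve(D1, D2)) + np.trace(np.linalg.solve(D2, D1))
    return float(0.5 * np.sqrt(max(tr - 6.0, 0.0)))


def geodesic_metric(D1: np.ndarray, D2: np.ndarray,
                    variant: str = "affine") -> float:
    """Riemannian geodesic distance between SPD tensors.

    ``variant='affine'`` (default) is the affine-invariant metric
    ``sqrt(sum_k ln^2 lambda_k(D1^-1 D2))``; ``variant='logeuclidean'``
    is ``||logm(D1) - logm(D2)||_F``. The two agree whenever D1 and D2
    commute.
    """
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    _check_spd(D1, "D1")
    _check_spd(D2, "D2")
    if variant == "affine":
        w = scipy.linalg.eigh(D2, D1, eigvals_only=True)
        return float(np.sqrt(np.sum(np.log(w) ** 2)))
    if variant == "logeuclidean":
        def _logm_spd(D):
            w, v = np.linalg.eigh(D)
            return (v * np.log(w)) @ v.T
        diff = _logm_spd(D1) - _logm_spd(D2)
        return float(np.sqrt(np.sum(diff * diff)))
    raise ValueError(f"unknown geodesic variant {variant!r}")


TENSOR_METRICS = {
    "euclidean": euclidean_metric,
    "jdivergence": jdivergence_metric,
    "geodesic": geodesic_metric,
}
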