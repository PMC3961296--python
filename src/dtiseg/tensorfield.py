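"""Tensor volumes, eigen-decomposition and per-voxel scalar features.

A diffusion-tensor field assigns every voxel a 3x3 symmetric positive
definite matrix ``D`` (units mm^2/s for measured data, unitless for
synthetic lattices). The eigenvalues of ``D`` describe the local geometry
of water diffusion; the eigenvector of the largest eigenvalue is the
principal orientation (an axis — its sign is arbitrary). From the sorted
eigenvalues ``l1 >= l2 >= l3 > 0`` three standard scalar features are
derived:

* mean diffusivity   ``MD = (l1 + l2 + l3) / 3``
* fractional anisotropy
  ``FA = sqrt(3/2) * ||l - MD|| / ||l||``, in [0, 1]
* volume ratio       ``VR = (l1 * l2 * l3) / MD^3``, in [0, 1]

MD measures overall diffusivity; FA and VR characterise anisotropy
(FA = 0, VR = 1 for isotropic tensors). Features are min-max normalised
to [0, 1] over the valid voxels of the field before any distance is
computed, so that each contributes on a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import nibabel as nib
import numpy as np

__all__ = [
    "TensorField", "TensorEigen", "VoxelFeatures",
    "eigendecompose", "reconstruct", "compute_features",
    "read_tensor_nifti", "write_tensor_nifti",
    "read_mask_nifti", "write_mask_nifti",
    "load_lattice", "save_lattice",
]

# upper-triangular component order used on disk: Dxx Dxy Dxz Dyy Dyz Dzz
_UPPER_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
# lower-triangular dialect: Dxx Dxy Dyy Dxz Dyz Dzz
_LOWER_TO_UPPER = (0, 1, 3, 2, 4, 5)

_SYM_RTOL = 1e-10
_DEGEN_RTOL = 1e-9


@dataclass
class TensorField:
    """Grid of 3x3 symmetric tensors with a validity mask.

    Parameters
    ----------
    tensors : ndarray, shape (*grid, 3, 3)
        Per-voxel tensor; grid may be 2-D or 3-D.
    valid_mask : ndarray of bool, shape (*grid,)
        True where the tensor is usable (finite, symmetric, SPD after the
        repair policy applied in :func:`eigendecompose`).
    voxel_size : tuple of float, optional
        Physical spacing per axis in mm.
    """

    tensors: np.ndarray
    valid_mask: np.ndarray
    voxel_size: tuple | None = None

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError(
                f"tensors must have trailing shape (3, 3), got {self.tensors.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.tensors.shape[:-2], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.tensors.shape[:-2]:
            raise ValueError("valid_mask shape does not match grid shape")

    @property
    def shape(self) -> tuple:
        return self.tensors.shape[:-2]

    @property
    def ndim_grid(self) -> int:
        return len(self.shape)

    @classmethod
    def from_components(cls, comps: np.ndarray, dialect: str = "upper",
                        voxel_size=None) -> "TensorField":
        """Build a field from 6-component voxel data.

        ``dialect='upper'`` expects (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz);
        ``dialect='lower'`` expects (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
        Voxels whose six components are all zero are marked invalid.
        """
        comps = np.asarray(comps, dtype=float)
        if comps.shape[-1] != 6:
            raise ValueError(
                "expected 6 components per voxel in upper-triangular order "
                f"(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz); got trailing dimension "
                f"{comps.shape[-1]}"
            )
        if dialect == "lower":
            comps = comps[..., _LOWER_TO_UPPER]
        elif dialect != "upper":
            raise ValueError(f"unknown dialect {dialect!r}")
        grid = comps.shape[:-1]
        t = np.empty(grid + (3, 3), dtype=float)
        for k, (i, j) in enumerate(_UPPER_IDX):
            t[..., i, j] = comps[..., k]
            t[..., j, i] = comps[..., k]
        valid = ~np.all(comps == 0.0, axis=-1)
        valid &= np.all(np.isfinite(comps), axis=-1)
        return cls(t, valid, voxel_size=voxel_size)

    def to_components(self) -> np.ndarray:
        """Return the (*grid, 6) upper-triangular component array."""
        comps = np.empty(self.shape + (6,), dtype=float)
        for k, (i, j) in enumerate(_UPPER_IDX):
            comps[..., k] = self.tensors[..., i, j]
        return comps


@dataclass
class TensorEigen:
    """Eigensystem of a tensor field.

    ``eigenvalues`` are sorted descending per voxel; ``principal_axis`` is
    the unit eigenvector of the largest eigenvalue. ``degenerate`` flags
    voxels where the two largest eigenvalues coincide (relative gap below
    1e-9) and the principal axis is therefore a deterministic but
    arbitrary choice within the eigenplane.
    """

    eigenvalues: np.ndarray   # (*grid, 3), descending
    principal_axis: np.ndarray  # (*grid, 3), unit norm on valid voxels
    valid_mask: np.ndarray
    degenerate: np.ndarray = dc_field(default=None)

    @property
    def shape(self):
        return self.eigenvalues.shape[:-1]


@dataclass
class VoxelFeatures:
    """Per-voxel scalar features and principal axes of a field.

    Raw MD/FA/VR plus their field-wise min-max normalisations (over valid
    voxels only). Normalisation is monotone, so feature ordering is
    preserved; a feature that is constant across the field normalises
    to 0 everywhere.
    """

    md: np.ndarray
    fa: np.ndarray
    vr: np.ndarray
    md_norm: np.ndarray
    fa_norm: np.ndarray
    vr_norm: np.ndarray
    principal_axis: np.ndarray
    valid_mask: np.ndarray

    def normalized(self) -> np.ndarray:
        """Stacked (*grid, 3) array of (md_norm, fa_norm, vr_norm)."""
        return np.stack([self.md_norm, self.fa_norm, self.vr_norm], axis=-1)


def eigendecompose(field: TensorField, repair: bool = True) -> TensorEigen:
    """Eigen-decompose every valid tensor of a field.

    Eigenvalues are returned sorted descending with the matching unit
    principal eigenvector. The SPD repair policy clamps eigenvalues in
    ``(-tau, tau]`` with ``tau = 1e-12 * l1`` up to ``tau``; a voxel with
    an eigenvalue below ``-tau`` is marked invalid in the returned mask
    (never silently zeroed).

    Raises
    ------
    ValueError
        If a valid voxel's tensor is asymmetric beyond 1e-10 relative
        tolerance; the error names the offending voxel index.
    """
    t = field.tensors
    valid = field.valid_mask.copy()

    asym = np.abs(t - np.swapaxes(t, -1, -2)).max(axis=(-1, -2))
    scale = np.abs(t).max(axis=(-1, -2))
    bad = valid & (asym > _SYM_RTOL * np.maximum(scale, 1e-300))
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"tensor at voxel {idx} is not symmetric "
                         f"(max asymmetry {asym[bad].max():.3e})")

    grid = field.shape
    evals = np.zeros(grid + (3,), dtype=float)
    axes = np.zeros(grid + (3,), dtype=float)
    degen = np.zeros(grid, dtype=bool)

    flat_idx = np.argwhere(valid)
    if flat_idx.size:
        sub = t[valid]                       # (n, 3, 3)
        w, v = np.linalg.eigh(sub)           # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        l1 = w[:, 0]
        if repair:
            tau = 1e-12 * np.maximum(l1, 0.0)
            irreparable = w[:, 2] < -tau
            w = np.where(w <= tau[:, None], tau[:, None], w)
            w[irreparable] = 0.0
        else:
            irreparable = w[:, 2] <= 0.0
        nonpos = w[:, 2] <= 0.0
        ok = ~(irreparable | nonpos)

        gap = np.abs(w[:, 0] - w[:, 1])
        degen_sub = gap <= _DEGEN_RTOL * np.maximum(np.abs(w[:, 0]), 1e-300)

        evals[valid] = w
        axes[valid] = v[:, :, 0]
        degen[valid] = degen_sub
        newmask = valid.copy()
        newmask[valid] = ok
        valid = newmask

    return TensorEigen(evals, axes, valid, degenerate=degen)


def reconstruct(eig: TensorEigen, basis: np.ndarray) -> np.ndarray:
    """Rebuild tensors from eigenvalues and a full eigenvector basis.

    ``basis`` has shape (*grid, 3, 3) with eigenvectors in columns,
    ordered to match ``eig.eigenvalues``. Mostly a testing aid for the
    decompose/reconstruct round trip.
    """
    lam = eig.eigenvalues
    return np.einsum("...ik,...k,...jk->...ij", basis, lam, basis)


def compute_features(eig: TensorEigen,
                     valid_mask: np.ndarray | None = None) -> VoxelFeatures:
    """Compute MD, FA, VR and their min-max normalisations.

    Normalisation statistics are taken over the valid voxels only; a voxel
    with MD = 0 is marked invalid (FA/VR undefined there). A feature that
    is constant over the field normalises to 0 to avoid 0/0.
    """
    if valid_mask is None:
        valid_mask = eig.valid_mask
    valid = valid_mask & eig.valid_mask

    lam = eig.eigenvalues
    md = lam.mean(axis=-1)

    valid = valid & (md > 0.0)

    norm_l = np.sqrt((lam ** 2).sum(axis=-1))
    dev = lam - md[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt((dev ** 2).sum(axis=-1)) / norm_l
        vr = lam.prod(axis=-1) / md ** 3
    fa = np.where(valid, np.clip(fa, 0.0, 1.0), 0.0)
    vr = np.where(valid, np.clip(vr, 0.0, 1.0), 0.0)
    md = np.where(valid, md, 0.0)

    def _minmax(x):
        out = np.zeros_like(x)
        if not np.any(valid):
            return out
        lo, hi = x[valid].min(), x[valid].max()
        if hi - lo > 0.0:
            out[valid] = (x[valid] - lo) / (hi - lo)
        return out

    return VoxelFeatures(
        md=md, fa=fa, vr=vr,
        md_norm=_minmax(md), fa_norm=_minmax(fa), vr_norm=_minmax(vr),
        principal_axis=eig.principal_axis,
        valid_mask=valid,
    )


# ---------------------------------------------------------------------------
# file I/O

def write_tensor_nifti(field: TensorField, path, dialect: str = "upper"):
    """Write a tensor field as a 6-component NIfTI volume.

    2-D grids are stored with a singleton third axis. Invalid voxels are
    written as all-zero components (the round-trip read marks them
    invalid again).
    """
    comps = field.to_components()
    comps = np.where(field.valid_mask[..., None], comps, 0.0)
    if dialect == "lower":
        inv = np.argsort(_LOWER_TO_UPPER)
        comps = comps[..., inv]
    elif dialect != "upper":
        raise ValueError(f"unknown dialect {dialect!r}")
    if comps.ndim == 3:  # 2-D grid -> pad to (X, Y, 1, 6)
        comps = comps[:, :, None, :]
    affine = np.eye(4)
    if field.voxel_size is not None:
        for i, s in enumerate(field.voxel_size[:3]):
            affine[i, i] = s
    nib.save(nib.Nifti1Image(comps, affine), str(path))


def read_tensor_nifti(path, dialect: str = "upper") -> TensorField:
    """Read a 6-component tensor NIfTI volume.

    A trailing singleton spatial axis (written for 2-D lattices) is
    squeezed away. ``dialect`` selects the on-disk component order; see
    :meth:`TensorField.from_components`.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(
            "expected a 4-D NIfTI with 6 components per voxel "
            "(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz upper-triangular order); "
            f"got shape {data.shape}"
        )
    if data.shape[2] == 1:
        data = data[:, :, 0, :]
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TensorField.from_components(data, dialect=dialect, voxel_size=vs)


def write_mask_nifti(mask: np.ndarray, path):
    """Write an integer mask/label volume (2-D grids get a singleton axis)."""
    arr = np.asarray(mask, dtype=np.int16)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))


def read_mask_nifti(path) -> np.ndarray:
    """Read an integer mask/label volume, squeezing a singleton third axis."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).astype(np.int64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    return arr


def save_lattice(field: TensorField, path):
    """Save a synthetic lattice as a plain ``.npz`` array bundle."""
    np.savez(path, tensors=field.tensors, valid_mask=field.valid_mask)


def load_lattice(path) -> TensorField:
    """Load a lattice written by :func:`save_lattice`."""
    with np.load(path) as z:
        return TensorField(z["tensors"], z["valid_mask"])
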