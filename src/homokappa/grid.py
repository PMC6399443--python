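"""Regular voxel grids with world affines, masks, and exact x-mirroring.

Everything downstream (MA, ALE, MHC, VMHC, VCC and difference maps) lives on a
:class:`VolumeGrid`.  The central geometric requirement is *mirror closure*:
for every in-mask voxel whose center sits at world ``(x, y, z)``, the voxel at
``(-x, y, z)`` must also be on the grid.  The world plane ``x = 0`` is the
anatomical midline (symmetric-template convention, RAS orientation), so
homotopic voxels are exact index permutations of each other and mirroring is
an involution with no interpolation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

#: recognised semantic tags for map values (stored in NIfTI description field)
VALUE_KINDS = (
    "MA_probability",
    "ALE",
    "kappa",
    "fisher_z",
    "zscore",
    "vcc",
    "difference",
    "binary",
    "generic",
)


class GridError(ValueError):
    """Raised for invalid grid geometry (non-invertible affine, no mirror...)."""


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """A 3-D regular grid: shape, voxel->world affine, boolean brain mask.

    Parameters
    ----------
    shape : tuple of 3 ints
    affine : (4, 4) array mapping voxel indices (i, j, k, 1) to world mm.
    mask : bool array of ``shape`` or None (None means all voxels in-mask).
    """

    shape: tuple
    affine: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GridError(f"shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GridError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GridError("affine is not invertible")
        mask = self.mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise GridError("mask shape does not match grid shape")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "mask", mask)

    # -- constructors ------------------------------------------------------

    @classmethod
    def symmetric(cls, shape, voxel_size=2.0, mask=None) -> "VolumeGrid":
        """A mirror-closed RAS grid centered on the midline.

        Voxel centers along x are placed symmetrically about the world plane
        x = 0 (for even counts no voxel lies exactly on the midline; for odd
        counts the central voxel is its own mirror).
        """
        shape = tuple(int(s) for s in shape)
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
        if np.any(vs <= 0):
            raise GridError("voxel_size must be positive")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vs)
        affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * vs
        return cls(shape, affine, mask)

    # -- geometry ----------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T

    def world_x(self) -> np.ndarray:
        """World x coordinate of each slab along axis 0 (requires x-aligned affine)."""
        self._require_x_aligned()
        i = np.arange(self.shape[0], dtype=float)
        return self.affine[0, 0] * i + self.affine[0, 3]

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of every voxel center."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.stack(idx, axis=-1).reshape(-1, 3)
        return self.voxel_to_world(pts).reshape(self.shape + (3,))

    def _require_x_aligned(self):
        a = self.affine
        if (abs(a[0, 1]) > 1e-9 or abs(a[0, 2]) > 1e-9
                or abs(a[1, 0]) > 1e-9 or abs(a[2, 0]) > 1e-9):
            raise GridError(
                "grid x-axis is not aligned with the world x-axis; "
                "resample onto an axis-aligned symmetric grid first")

    # -- mirroring ---------------------------------------------------------

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation along axis 0 implementing x -> -x.

        Raises
        ------
        GridError
            If the grid is not mirror-closed for its in-mask voxels.
        """
        xs = self.world_x()
        a, t = self.affine[0, 0], self.affine[0, 3]
        j = (-xs - t) / a
        jr = np.rint(j).astype(int)
        ok = (np.abs(j - jr) < 1e-6) & (jr >= 0) & (jr < self.shape[0])
        if not ok.all():
            bad = np.where(~ok)[0]
            # tolerate missing mirrors only for slabs with no in-mask voxels
            if self.mask[bad].any():
                raise GridError(
                    "grid is not mirror-closed: in-mask voxels at world "
                    f"x={xs[bad][self.mask[bad].any(axis=(1, 2))][:3]} have no "
                    "on-grid mirror; resample onto a symmetric grid")
            jr[bad] = bad  # identity on empty slabs
        return jr

    def is_mirror_closed(self) -> bool:
        try:
            self.mirror_permutation()
            return True
        except GridError:
            return False

    def mirror_mask(self) -> np.ndarray:
        """The mask mirrored about the midline."""
        return self.mask[self.mirror_permutation(), :, :]

    def with_mask(self, mask) -> "VolumeGrid":
        return VolumeGrid(self.shape, self.affine, mask)

    def same_geometry(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclasses.dataclass(frozen=True)
class VoxelMap:
    """A scalar field on a :class:`VolumeGrid` with a semantic value kind."""

    grid: VolumeGrid
    values: np.ndarray
    value_kind: str = "generic"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise GridError("values shape does not match grid shape")
        if self.value_kind not in VALUE_KINDS:
            raise GridError(f"unknown value_kind {self.value_kind!r}")
        object.__setattr__(self, "values", values)

    def masked_values(self) -> np.ndarray:
        return self.values[self.grid.mask]

    def validate_finite(self) -> None:
        if not np.isfinite(self.values[self.grid.mask]).all():
            raise GridError("non-finite values inside the mask")


def mirror_x(m: VoxelMap) -> VoxelMap:
    """Reflect a map about the midsagittal plane (world x = 0).

    The output value at world (x, y, z) equals the input value at (-x, y, z);
    the mask is mirrored alongside the values.  On mirror-closed grids this is
    an exact involution (pure index permutation, no interpolation).
    """
    perm = m.grid.mirror_permutation()
    vals = m.values[perm, :, :]
    mask = m.grid.mask[perm, :, :]
    return VoxelMap(m.grid.with_mask(mask), vals, m.value_kind)
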