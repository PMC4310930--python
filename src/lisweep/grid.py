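"""Sampling grids and t-statistic maps.

Everything downstream of the simulator — masks, voxel counts, mirroring —
is defined in world (MNI-convention) millimetres: x increases to the
subject's right, the interhemispheric midline is the plane x = 0.  A
:class:`Grid` couples a lattice shape to the voxel-to-world affine so that
every module rasterises geometry through the same transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Grid", "StatMap", "default_grid"]

#: half-width (mm) of the band around x = 0 treated as midline
MIDLINE_TOL = 1e-6


@dataclass(frozen=True)
class Grid:
    """A 3-D lattice with a voxel-index-to-world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, invertible

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel centre, one 3-D array per axis."""
        ii, jj, kk = np.meshgrid(
            *(np.arange(s) for s in self.shape), indexing="ij"
        )
        A, b = self.affine[:3, :3], self.affine[:3, 3]
        x = A[0, 0] * ii + A[0, 1] * jj + A[0, 2] * kk + b[0]
        y = A[1, 0] * ii + A[1, 1] * jj + A[1, 2] * kk + b[1]
        z = A[2, 0] * ii + A[2, 1] * jj + A[2, 2] * kk + b[2]
        return x, y, z

    def world_x(self) -> np.ndarray:
        return self.world_coords()[0]

    def world_to_voxel(self, xyz_mm) -> np.ndarray:
        """Map world mm to (fractional) voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        homo = np.c_[xyz, np.ones(len(xyz))]
        return (homo @ inv.T)[:, :3]

    def left_hemisphere(self) -> np.ndarray:
        """Boolean mask of voxels strictly left of the midline (world x < 0)."""
        return self.world_x() < -MIDLINE_TOL

    def right_hemisphere(self) -> np.ndarray:
        return self.world_x() > MIDLINE_TOL

    def is_mirror_symmetric(self) -> bool:
        """True if the voxel-centre x coordinates are symmetric about 0.

        Requires a diagonal orientation (world x varies along the first
        index only), which covers every grid this package constructs.
        """
        A = self.affine[:3, :3]
        off_diag = A - np.diag(np.diag(A))
        if np.abs(off_diag).max() > 1e-9:
            return False
        xs = self.affine[0, 0] * np.arange(self.shape[0]) + self.affine[0, 3]
        return bool(np.allclose(np.sort(xs), np.sort(-xs), atol=1e-9))

    def mirror_x(self, values: np.ndarray) -> np.ndarray:
        """Reflect a lattice through the x = 0 plane (world space).

        Only defined on mirror-symmetric grids, where the reflection is an
        exact permutation of voxels (a flip of the first index).
        """
        if not self.is_mirror_symmetric():
            raise ValueError("grid is not mirror-symmetric about x = 0")
        if values.shape[:3] != self.shape:
            raise ValueError("array shape does not match grid")
        return values[::-1, ...].copy()

    def same_geometry(self, other: "Grid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


def default_grid(
    shape: tuple[int, int, int] = (64, 64, 40), voxel_mm: float = 3.0
) -> Grid:
    """The analysis grid: isotropic voxels, world origin at the grid centre.

    With the default 3 mm voxels and even extents, voxel-centre x
    coordinates come in exact +/- pairs and none lies on the midline, so
    hemisphere masks partition the grid and world-space mirroring is an
    exact voxel permutation.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_mm)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * float(voxel_mm)
    return Grid(shape=shape, affine=affine)


@dataclass
class StatMap:
    """A 3-D lattice of t-statistics with its grid and residual dof."""

    values: np.ndarray
    grid: Grid
    dof: int
    n_zero_variance: int = 0  # voxels whose series had zero variance (t forced to 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.dof < 1:
            raise ValueError(f"dof must be >= 1, got {self.dof}")

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    def mirrored(self) -> "StatMap":
        """The map reflected through the midline (left/right exchanged)."""
        return StatMap(
            values=self.grid.mirror_x(self.values),
            grid=self.grid,
            dof=self.dof,
            n_zero_variance=self.n_zero_variance,
        )

    # -- I/O: NIfTI volume plus a JSON sidecar carrying the dof ------------

    def to_filename(self, path: str | Path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine)
        nib.save(img, path)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        meta = {"dof": int(self.dof), "n_zero_variance": int(self.n_zero_variance)}
        Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_filename(cls, path: str | Path) -> "StatMap":
        path = Path(path)
        img = nib.load(path)
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
        meta = json.loads(sidecar.read_text())
        data = np.asarray(img.get_fdata(), dtype=float)
        return cls(
            values=data,
            grid=Grid(shape=data.shape, affine=np.asarray(img.affine)),
            dof=int(meta["dof"]),
            n_zero_variance=int(meta.get("n_zero_variance", 0)),
        )
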