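"""Language-network ROI masks: MNI-seeded spheres and mirrored homologues.

Left-hemisphere seeds are rasterised as closed balls on the analysis grid
(a voxel belongs to a sphere iff its centre lies within radius_mm of the
seed, in world mm); right-hemisphere homologues are obtained by negating
the world x coordinate of the seed and rasterising again, which is correct
for any affine.  Whole-hemisphere masks split the grid at the x = 0 plane,
with midline voxels excluded from both sides.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .grid import MIDLINE_TOL, Grid

__all__ = [
    "RoiSpec",
    "NetworkMasks",
    "sphere_mask",
    "mirror_spec",
    "build_network",
    "load_roi_table",
    "default_roi_table",
]

_MIRROR_TAG = "_R"


@dataclass(frozen=True)
class RoiSpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))
        if self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.center_mm[0] == 0:
            raise ValueError(
                f"ROI '{self.name}' sits on the midline (x = 0) and cannot be mirrored"
            )


def mirror_spec(roi: RoiSpec) -> RoiSpec:
    """The homologous ROI in the opposite hemisphere: (x, y, z) -> (-x, y, z).

    Applying it twice returns the original spec (the hemisphere tag on the
    name toggles).
    """
    x, y, z = roi.center_mm
    if roi.name.endswith(_MIRROR_TAG):
        name = roi.name[: -len(_MIRROR_TAG)]
    else:
        name = roi.name + _MIRROR_TAG
    return RoiSpec(name=name, center_mm=(-x, y, z), radius_mm=roi.radius_mm)


def sphere_mask(center_mm, radius_mm: float, grid: Grid) -> np.ndarray:
    """Closed-ball mask: voxel centres within radius_mm of center_mm.

    radius 0 degenerates to the single voxel containing the point (ties on
    a voxel boundary broken toward the lower index).  A sphere wholly
    outside the grid yields an empty mask with a warning.
    """
    center = tuple(float(c) for c in center_mm)
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if radius_mm == 0:
        frac = grid.world_to_voxel(center)[0]
        idx = np.ceil(frac - 0.5).astype(int)  # ties -> lower index
        mask = np.zeros(grid.shape, dtype=bool)
        if all(0 <= idx[a] < grid.shape[a] for a in range(3)):
            mask[tuple(idx)] = True
        else:
            warnings.warn(f"point {center} lies outside the grid; empty mask")
        return mask
    x, y, z = grid.world_coords()
    mask = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius_mm**2
    if not mask.any():
        warnings.warn(
            f"sphere at {center} (r={radius_mm} mm) lies wholly outside the grid; empty mask"
        )
    return mask


@dataclass
class NetworkMasks:
    """Paired left/right masks on the analysis grid.

    Disjoint by construction; voxels on the midline plane belong to
    neither side.
    """

    left: np.ndarray
    right: np.ndarray
    grid: Grid
    mode: str
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.left.shape != self.grid.shape or self.right.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if (self.left & self.right).any():
            raise ValueError("left and right masks overlap")


def build_network(
    rois: list[RoiSpec] | None, grid: Grid, mode: str = "network"
) -> NetworkMasks:
    """Build the paired masks.

    network mode: left = union of the seed spheres, right = union of their
    mirrored homologues (the input list must be left-seeded, x < 0).
    hemispheric mode: left/right = all voxels with world x strictly
    negative/positive.
    """
    if mode not in ("network", "hemispheric"):
        raise ValueError(f"mode must be 'network' or 'hemispheric', got '{mode}'")
    wx = grid.world_x()
    if mode == "hemispheric":
        return NetworkMasks(
            left=wx < -MIDLINE_TOL,
            right=wx > MIDLINE_TOL,
            grid=grid,
            mode=mode,
            provenance=("hemisphere",),
        )
    if not rois:
        raise ValueError("network mode requires a non-empty ROI list")
    for r in rois:
        if r.center_mm[0] >= 0:
            raise ValueError(
                f"ROI '{r.name}' has x = {r.center_mm[0]} >= 0; the input table "
                "must contain left-hemisphere seeds only"
            )
    left = np.zeros(grid.shape, dtype=bool)
    right = np.zeros(grid.shape, dtype=bool)
    for r in rois:
        left |= sphere_mask(r.center_mm, r.radius_mm, grid)
        right |= sphere_mask(mirror_spec(r).center_mm, r.radius_mm, grid)
    # spheres may bleed across x = 0; clip to keep sides disjoint and the
    # midline plane out of both
    left &= wx < -MIDLINE_TOL
    right &= wx > MIDLINE_TOL
    return NetworkMasks(
        left=left, right=right, grid=grid, mode=mode, provenance=tuple(r.name for r in rois)
    )


def load_roi_table(path: str | Path) -> list[RoiSpec]:
    """Read a JSON ROI table ({name, x, y, z, radius_mm} records)."""
    obj = json.loads(Path(path).read_text())
    records = obj["rois"] if isinstance(obj, dict) else obj
    return [
        RoiSpec(
            name=r["name"],
            center_mm=(r["x"], r["y"], r["z"]),
            radius_mm=float(r.get("radius_mm", 5.0)),
        )
        for r in records
    ]


def default_roi_table() -> list[RoiSpec]:
    """The packaged default left language-network seeds (substitutable)."""
    with resources.files("lisweep.data").joinpath("language_rois.json").open() as fh:
        obj = json.load(fh)
    return [
        RoiSpec(name=r["name"], center_mm=(r["x"], r["y"], r["z"]), radius_mm=float(r.get("radius_mm", 5.0)))
        for r in obj["rois"]
    ]
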