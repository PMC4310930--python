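"""Synthetic block-design BOLD cohorts with known ground-truth lateralization.

The generator inverts the analysis model: inside declared activation
clusters the signal is baseline x (1 + amplitude x HRF-convolved boxcar),
independent Gaussian noise is added everywhere (as a fraction of baseline,
so amplitudes read as percent signal change), and a small linear leakage of
six smooth rigid-motion nuisance series contaminates every voxel so that
motion regression has something real to remove.  Cluster membership is
rasterised through the same affine the analysis side uses, so the
ground-truth mask and any downstream mask agree voxel for voxel.

Temporal autocorrelation is deliberately not modelled: every
calibration test downstream relies on exchangeable Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .grid import Grid, StatMap, default_grid

__all__ = [
    "Paradigm",
    "ActivationCluster",
    "SubjectSpec",
    "CohortSpec",
    "BoldSeries",
    "SubjectData",
    "make_paradigm",
    "simulate_bold",
    "simulate_stat_map",
    "simulate_cohort",
    "cohort_manifest",
    "MOTION_COLUMNS",
]

MOTION_COLUMNS = ["x", "y", "z", "pitch", "roll", "yaw"]


@dataclass(frozen=True)
class Paradigm:
    """Block-design timing: each cycle is rest first, then task."""

    rest_s: float
    task_s: float
    cycles: int
    tr: float

    @property
    def cycle_s(self) -> float:
        return self.rest_s + self.task_s

    @property
    def total_s(self) -> float:
        return self.cycles * self.cycle_s

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_s / self.tr))

    def boxcar(self) -> np.ndarray:
        """Task indicator sampled at volume onsets (0 = rest, 1 = task)."""
        t = np.arange(self.n_volumes) * self.tr
        return ((t % self.cycle_s) >= self.rest_s - 1e-9).astype(float)

    def to_dict(self) -> dict:
        return {
            "rest_s": self.rest_s,
            "task_s": self.task_s,
            "cycles": self.cycles,
            "tr": self.tr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Paradigm":
        return make_paradigm(d["rest_s"], d["task_s"], int(d["cycles"]), d["tr"])


def make_paradigm(rest_s: float, task_s: float, cycles: int, tr: float) -> Paradigm:
    """Validate timings and build a :class:`Paradigm`.

    The cycle length must be a whole number of TRs so that the number of
    volumes is an integer and block edges fall on volume boundaries.
    """
    for name, v in [("rest_s", rest_s), ("task_s", task_s), ("cycles", cycles), ("tr", tr)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    cycle = rest_s + task_s
    if abs(cycle / tr - round(cycle / tr)) > 1e-9:
        raise ValueError(
            f"cycle length rest_s + task_s = {cycle} s is not divisible by tr = {tr} s"
        )
    return Paradigm(rest_s=float(rest_s), task_s=float(task_s), cycles=int(cycles), tr=float(tr))


@dataclass(frozen=True)
class ActivationCluster:
    """A spherical patch of task-locked signal.

    ``amplitude`` is the peak percent signal change as a fraction of
    baseline (0.02 = 2%).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class SubjectSpec:
    clusters: tuple[ActivationCluster, ...]
    noise_sd: float = 0.02  # fraction of baseline
    baseline: float = 1000.0
    motion_sd: float = 0.5  # mm / degrees
    motion_leak: float = 0.01  # fraction of baseline per unit standardized motion
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class BoldSeries:
    """A 4-D BOLD series (x, y, z, time) on a grid, with its paradigm."""

    data: np.ndarray
    grid: Grid
    paradigm: Paradigm

    def __post_init__(self) -> None:
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError("BOLD spatial shape does not match grid")
        if self.data.shape[3] != self.paradigm.n_volumes:
            raise ValueError("BOLD volume count does not match paradigm")

    def to_filename(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine), path)


@dataclass
class SubjectData:
    index: int
    spec: SubjectSpec
    bold: BoldSeries
    motion: pd.DataFrame
    truth_mask: np.ndarray


def _convolved_regressor(paradigm: Paradigm) -> np.ndarray:
    """HRF-convolved boxcar, peak-normalized so amplitudes read as PSC."""
    from .glm import hrf  # local import: glm also imports Paradigm from here

    box = paradigm.boxcar()
    t = np.arange(len(box)) * paradigm.tr
    kernel = hrf(t)
    reg = np.convolve(box, kernel)[: len(box)]
    peak = reg.max()
    return reg / peak if peak > 0 else reg


def _motion_table(rng: np.random.Generator, n: int, motion_sd: float) -> pd.DataFrame:
    """Six smooth low-frequency rigid-motion series (mm / degrees)."""
    series = {}
    for col in MOTION_COLUMNS:
        raw = gaussian_filter1d(rng.standard_normal(n + 40), sigma=8.0)[20:-20]
        sd = raw.std()
        series[col] = motion_sd * (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(series)


def simulate_bold(
    spec: SubjectSpec, paradigm: Paradigm, grid: Grid | None = None
) -> SubjectData:
    """Generate one subject: BOLD series, motion table, ground-truth mask.

    Bit-identical output for identical (spec, paradigm, grid).
    """
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(spec.seed)
    n_vol = paradigm.n_volumes
    reg = _convolved_regressor(paradigm)

    x, y, z = grid.world_coords()
    amp = np.zeros(grid.shape)
    truth = np.zeros(grid.shape, dtype=bool)
    for cl in spec.clusters:
        cx, cy, cz = cl.center_mm
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= cl.radius_mm**2
        if not inside.any():
            raise ValueError(
                f"cluster at {cl.center_mm} (r={cl.radius_mm} mm) lies entirely "
                "outside the grid; ground truth would be silently lost"
            )
        truth |= inside
        amp = np.where(inside, np.maximum(amp, cl.amplitude), amp)

    # task-locked signal: baseline x (1 + amplitude x regressor)
    data = spec.baseline * (1.0 + amp[..., None] * reg[None, None, None, :])

    motion = _motion_table(rng, n_vol, spec.motion_sd)
    if spec.motion_leak > 0 and spec.motion_sd > 0:
        weights = rng.standard_normal(6)
        zscored = (motion - motion.mean()) / motion.std().replace(0.0, 1.0)
        nuisance = (zscored.to_numpy() @ weights) / np.sqrt(6.0)
        data = data + spec.baseline * spec.motion_leak * nuisance[None, None, None, :]

    if spec.noise_sd > 0:
        data = data + spec.baseline * spec.noise_sd * rng.standard_normal(data.shape)

    bold = BoldSeries(data=data, grid=grid, paradigm=paradigm)
    return SubjectData(index=spec.seed, spec=spec, bold=bold, motion=motion, truth_mask=truth)


def simulate_stat_map(
    left_voxels: int,
    right_voxels: int,
    active_t: float,
    inactive_t: float = 0.0,
    grid: Grid | None = None,
    dof: int = 100,
) -> StatMap:
    """A t-map with exact suprathreshold counts per hemisphere.

    Thresholding at any tau with inactive_t < tau <= active_t recovers
    exactly (left_voxels, right_voxels).  Active voxels are assigned in
    flat-index order within each off-midline hemisphere, so the layout is
    deterministic.
    """
    grid = grid if grid is not None else default_grid()
    if left_voxels < 0 or right_voxels < 0:
        raise ValueError("voxel counts must be non-negative")
    if active_t <= inactive_t:
        raise ValueError(
            f"active_t ({active_t}) must exceed inactive_t ({inactive_t})"
        )
    values = np.full(grid.shape, float(inactive_t))
    for n_req, hemi, side in [
        (left_voxels, grid.left_hemisphere(), "left"),
        (right_voxels, grid.right_hemisphere(), "right"),
    ]:
        idx = np.flatnonzero(hemi.ravel())
        if n_req > idx.size:
            raise ValueError(
                f"{side} hemisphere has only {idx.size} off-midline voxels, "
                f"cannot place {n_req}"
            )
        values.ravel()[idx[:n_req]] = float(active_t)
    return StatMap(values=values, grid=grid, dof=dof)


@dataclass(frozen=True)
class CohortSpec:
    """A cohort whose subjects share geometry but draw cluster amplitudes.

    Left and right activation sits at mirrored cluster centres; per-subject
    amplitudes are drawn from the two normal distributions (clipped at 0).
    A zero right distribution (mean 0, sd 0) yields strictly left-sided
    ground truth.
    """

    n_subjects: int
    left_amplitude: tuple[float, float] = (0.03, 0.005)  # (mean, sd), PSC fraction
    right_amplitude: tuple[float, float] = (0.015, 0.0025)
    cluster_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    cluster_radius_mm: float = 12.0
    noise_sd: float = 0.02
    baseline: float = 1000.0
    motion_sd: float = 0.5
    motion_leak: float = 0.01
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.cluster_centers_mm is not None:
            object.__setattr__(
                self,
                "cluster_centers_mm",
                tuple(tuple(float(c) for c in ctr) for ctr in self.cluster_centers_mm),
            )

    @property
    def grid(self) -> Grid:
        return default_grid(self.grid_shape, self.voxel_mm)

    def centers(self) -> tuple[tuple[float, float, float], ...]:
        if self.cluster_centers_mm is not None:
            return self.cluster_centers_mm
        from .roi import default_roi_table

        return tuple(r.center_mm for r in default_roi_table())


def _subject_seed(cohort_seed: int, index: int) -> int:
    # stable child stream per (seed, index); kept below 2**31
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0] % (2**31))


def cohort_manifest(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject drawn amplitudes and seeds, reproducible from spec.seed."""
    rows = []
    for i in range(spec.n_subjects):
        sseed = _subject_seed(spec.seed, i)
        draw = np.random.default_rng([spec.seed, i, 1])
        left = max(0.0, draw.normal(*spec.left_amplitude)) if spec.left_amplitude[0] > 0 or spec.left_amplitude[1] > 0 else 0.0
        right = max(0.0, draw.normal(*spec.right_amplitude)) if spec.right_amplitude[0] > 0 or spec.right_amplitude[1] > 0 else 0.0
        rows.append(
            {"subject": i, "left_amplitude": left, "right_amplitude": right, "seed": sseed}
        )
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec, paradigm: Paradigm):
    """Yield :class:`SubjectData` per subject (lazily; volumes are large).

    Each subject is reproducible from (spec.seed, index) alone; the
    manifest of drawn amplitudes is available separately through
    :func:`cohort_manifest` without generating any volume.
    """
    manifest = cohort_manifest(spec)
    grid = spec.grid
    centers = spec.centers()
    for row in manifest.itertuples():
        clusters = []
        if row.left_amplitude > 0:
            clusters += [
                ActivationCluster(center_mm=c, radius_mm=spec.cluster_radius_mm, amplitude=row.left_amplitude)
                for c in centers
            ]
        if row.right_amplitude > 0:
            clusters += [
                ActivationCluster(
                    center_mm=(-c[0], c[1], c[2]),
                    radius_mm=spec.cluster_radius_mm,
                    amplitude=row.right_amplitude,
                )
                for c in centers
            ]
        sub = SubjectSpec(
            clusters=tuple(clusters),
            noise_sd=spec.noise_sd,
            baseline=spec.baseline,
            motion_sd=spec.motion_sd,
            motion_leak=spec.motion_leak,
            seed=int(row.seed),
        )
        data = simulate_bold(sub, paradigm, grid)
        data.index = int(row.subject)
        yield data
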