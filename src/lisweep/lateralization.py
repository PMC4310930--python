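"""Lateralization index (LI) across a continuum of statistical thresholds.

For a t-map and a left/right mask pair, the LI at threshold tau is

    LI = (VL - VR) / (VL + VR)

where VL and VR are the counts of active voxels (t >= tau, positive tail:
task > rest) in the left and right masks.  LI = +1 is fully left-dominant,
-1 fully right-dominant.  The categorisation scale is

    LI >  0.2          left-lateralized
    -0.2 <= LI <= 0.2  bilateral
    LI < -0.2          right-lateralized

with the endpoints +/-1 assigned to left/right (an all-left map is
maximally left-lateralized).  When no voxel survives on either side the LI
is undefined and reported as 'undetermined' — never silently as 0, which
would fake bilaterality on an empty map.

The default threshold sweep is t in {2, 2.67, 3.5, 4}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import Grid, StatMap
from .roi import NetworkMasks, RoiSpec, build_network, mirror_spec, sphere_mask

__all__ = [
    "DEFAULT_THRESHOLDS",
    "LiRecord",
    "LiCurve",
    "count_active",
    "compute_li",
    "categorize",
    "li_curve",
    "roi_pair_lis",
    "LateralizationSweep",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (2.0, 2.67, 3.5, 4.0)

LEFT = "left"
RIGHT = "right"
BILATERAL = "bilateral"
UNDETERMINED = "undetermined"


def count_active(
    stat_map: StatMap, mask: np.ndarray, threshold: float, two_sided: bool = False
) -> int:
    """Count suprathreshold voxels (t >= threshold, inclusive) inside a mask.

    Positive-tail by default; ``two_sided=True`` counts |t| >= threshold.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stat_map.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map shape {stat_map.values.shape}"
        )
    vals = np.abs(stat_map.values) if two_sided else stat_map.values
    return int(np.count_nonzero(mask & (vals >= threshold)))


def compute_li(v_left: int, v_right: int) -> float | None:
    """Exact LI from integer counts; None (undefined) when both are zero."""
    if v_left < 0 or v_right < 0:
        raise ValueError(f"voxel counts must be non-negative, got ({v_left}, {v_right})")
    total = v_left + v_right
    if total == 0:
        return None
    return float(Fraction(v_left - v_right, total))


def categorize(li: float | None) -> str:
    """Map an LI value (or undefined) to its lateralization category."""
    if li is None:
        return UNDETERMINED
    if not -1.0 - 1e-12 <= li <= 1.0 + 1e-12:
        raise ValueError(f"LI must lie in [-1, 1], got {li}")
    if li > 0.2:
        return LEFT
    if li < -0.2:
        return RIGHT
    return BILATERAL


@dataclass(frozen=True)
class LiRecord:
    threshold: float
    v_left: int
    v_right: int
    li: float | None
    category: str
    name: str = ""  # ROI-pair label when applicable


@dataclass
class LiCurve:
    """Per-subject LI as a function of threshold (ascending)."""

    records: list[LiRecord]
    subject: str | int | None = None
    group: str | None = None
    task: str | None = None

    @property
    def thresholds(self) -> list[float]:
        return [r.threshold for r in self.records]

    def li_at(self, threshold: float) -> float | None:
        for r in self.records:
            if r.threshold == threshold:
                return r.li
        raise KeyError(f"no record at threshold {threshold}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject,
                "group": self.group,
                "task": self.task,
                "threshold": r.threshold,
                "v_left": r.v_left,
                "v_right": r.v_right,
                "li": np.nan if r.li is None else r.li,
                "category": r.category,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def _validate_thresholds(thresholds) -> tuple[float, ...]:
    ths = tuple(float(t) for t in thresholds)
    if not ths:
        raise ValueError("threshold list must be non-empty")
    if any(b <= a for a, b in zip(ths, ths[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {ths}")
    return ths


def li_curve(
    stat_map: StatMap,
    masks: NetworkMasks,
    thresholds=DEFAULT_THRESHOLDS,
    two_sided: bool = False,
    subject=None,
    group: str | None = None,
    task: str | None = None,
) -> LiCurve:
    """Sweep the thresholds and emit one LiRecord per threshold."""
    ths = _validate_thresholds(thresholds)
    if not masks.grid.same_geometry(stat_map.grid):
        raise ValueError("masks and stat map are on different grids")
    records = []
    prev_l = prev_r = None
    for tau in ths:
        vl = count_active(stat_map, masks.left, tau, two_sided=two_sided)
        vr = count_active(stat_map, masks.right, tau, two_sided=two_sided)
        if prev_l is not None and (vl > prev_l or vr > prev_r):
            raise AssertionError("suprathreshold counts increased with threshold")
        prev_l, prev_r = vl, vr
        li = compute_li(vl, vr)
        records.append(
            LiRecord(threshold=tau, v_left=vl, v_right=vr, li=li, category=categorize(li))
        )
    return LiCurve(records=records, subject=subject, group=group, task=task)


def roi_pair_lis(
    stat_map: StatMap,
    rois: list[RoiSpec],
    threshold: float,
    two_sided: bool = False,
) -> tuple[list[LiRecord], float | None]:
    """Per ROI-pair LI (seed sphere vs mirrored homologue) at one threshold.

    Returns the per-pair records and the mean LI over pairs with at least
    one active voxel; pairs with empty counts are 'undetermined' and
    excluded from the mean, which is None if every pair is empty.
    """
    if not rois:
        raise ValueError("ROI list must be non-empty")
    grid = stat_map.grid
    records = []
    defined = []
    for r in rois:
        if r.center_mm[0] >= 0:
            raise ValueError(f"ROI '{r.name}' is not left-seeded (x >= 0)")
        lmask = sphere_mask(r.center_mm, r.radius_mm, grid)
        rmask = sphere_mask(mirror_spec(r).center_mm, r.radius_mm, grid)
        vl = count_active(stat_map, lmask, threshold, two_sided=two_sided)
        vr = count_active(stat_map, rmask, threshold, two_sided=two_sided)
        li = compute_li(vl, vr)
        records.append(
            LiRecord(
                threshold=threshold, v_left=vl, v_right=vr, li=li,
                category=categorize(li), name=r.name,
            )
        )
        if li is not None:
            defined.append(li)
    mean_li = float(np.mean(defined)) if defined else None
    return records, mean_li


class LateralizationSweep(BaseEstimator, TransformerMixin):
    """Transformer: t-statistic maps -> per-subject LI-by-threshold table.

    Parameters
    ----------
    thresholds : sequence of float, default (2, 2.67, 3.5, 4)
        Ascending t thresholds to sweep.
    mode : {'hemispheric', 'network'}, default 'hemispheric'
        Whole-hemisphere masks, or the union of the ROI seed spheres and
        their mirrored homologues.
    rois : list of RoiSpec or None
        Seeds for network mode; the packaged defaults when None.
    two_sided : bool, default False
        Count |t| >= tau instead of the positive tail.
    """

    def __init__(self, thresholds=DEFAULT_THRESHOLDS, mode: str = "hemispheric",
                 rois: list[RoiSpec] | None = None, two_sided: bool = False):
        self.thresholds = thresholds
        self.mode = mode
        self.rois = rois
        self.two_sided = two_sided

    def fit(self, X, y=None) -> "LateralizationSweep":
        """Build the masks from the grid of the first map (or a Grid)."""
        first = X[0] if isinstance(X, (list, tuple)) else X
        grid = first.grid if isinstance(first, StatMap) else first
        if not isinstance(grid, Grid):
            raise TypeError("fit expects StatMap(s) or a Grid")
        rois = self.rois
        if rois is None and self.mode == "network":
            from .roi import default_roi_table

            rois = default_roi_table()
        self.masks_ = build_network(rois, grid, mode=self.mode)
        self.thresholds_ = _validate_thresholds(self.thresholds)
        return self

    def transform(self, X) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "masks_")
        maps = X if isinstance(X, (list, tuple)) else [X]
        frames = []
        for i, sm in enumerate(maps):
            curve = li_curve(
                sm, self.masks_, thresholds=self.thresholds_,
                two_sided=self.two_sided, subject=i,
            )
            frames.append(curve.to_frame())
        return pd.concat(frames, ignore_index=True)
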