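"""Voxel-wise block-design GLM producing t-statistic maps.

The model for each voxel time series y is ordinary least squares on a
design containing the HRF-convolved task boxcar (the only tested column),
six mean-centred rigid-motion nuisance regressors, an optional linear
drift, and an intercept.  The map value is t = beta_task / SE(beta_task)
with residual dof = rows - rank(design), carried on the StatMap so that
thresholds can be expressed either as raw t values or as tail
probabilities of Student's t.

No prewhitening / AR modelling: the synthetic noise is white by
construction, and the calibration tests assume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .grid import Grid, StatMap
from .synthetic import MOTION_COLUMNS, BoldSeries, Paradigm

__all__ = ["hrf", "build_design", "fit_glm", "smooth", "DesignMatrix", "BlockDesignGLM"]

log = logging.getLogger(__name__)

# canonical double-gamma: response peak 6 (gamma shape), undershoot 16,
# undershoot ratio 1/6; unit scale in seconds
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def _double_gamma(t: np.ndarray) -> np.ndarray:
    from scipy.stats import gamma

    return gamma.pdf(t, _PEAK_SHAPE) - _UNDERSHOOT_RATIO * gamma.pdf(t, _UNDERSHOOT_SHAPE)


@lru_cache(maxsize=1)
def _hrf_peak_value() -> float:
    dense = np.arange(0.0, 32.0, 0.01)
    return float(_double_gamma(dense).max())


def hrf(time_s) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1.

    Rises from 0 at stimulus onset to a peak near 5 s, followed by a
    shallow undershoot that has essentially resolved by 30 s.
    """
    t = np.asarray(time_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is defined for time >= 0")
    return _double_gamma(t) / _hrf_peak_value()


@dataclass
class DesignMatrix:
    """Named regressors after initial-volume dropping; task column first."""

    frame: pd.DataFrame
    drop_initial: int
    dropped_columns: tuple[str, ...] = ()

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    @property
    def task_index(self) -> int:
        return int(self.frame.columns.get_loc("task"))

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    @property
    def dof(self) -> int:
        return self.n_timepoints - self.rank


def _reject_rank_deficiency(frame: pd.DataFrame) -> None:
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name the most collinear column pair in the error
    Xn = X - X.mean(axis=0)
    norms = np.linalg.norm(Xn, axis=0)
    norms[norms == 0] = 1.0
    corr = np.abs((Xn / norms).T @ (Xn / norms))
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(corr), corr.shape)
    raise ValueError(
        f"design matrix is rank-deficient; most collinear columns: "
        f"'{frame.columns[i]}' and '{frame.columns[j]}'"
    )


def build_design(
    paradigm: Paradigm,
    motion: pd.DataFrame | None = None,
    drop_initial: int = 3,
    drift: bool = True,
) -> DesignMatrix:
    """Assemble the GLM design for a paradigm and motion table.

    The task regressor is the boxcar convolved with :func:`hrf` at the TR.
    The first ``drop_initial`` rows (pre-steady-state volumes) are removed
    from every column.  Motion columns are mean-centred; columns left with
    zero variance (e.g. a motionless simulation) are dropped with a log
    notice rather than breaking the fit.
    """
    if drop_initial < 0:
        raise ValueError("drop_initial must be >= 0")
    n_vol = paradigm.n_volumes
    box = paradigm.boxcar()
    t = np.arange(n_vol) * paradigm.tr
    task = np.convolve(box, hrf(t))[:n_vol]
    peak = task.max()
    if peak > 0:
        task = task / peak

    cols: dict[str, np.ndarray] = {"task": task}
    if motion is not None:
        if len(motion) != n_vol:
            raise ValueError(
                f"motion table has {len(motion)} rows but paradigm has {n_vol} volumes"
            )
        for c in motion.columns:
            cols[f"motion_{c}"] = np.asarray(motion[c], dtype=float)
    if drift:
        cols["drift"] = np.linspace(-0.5, 0.5, n_vol)
    cols["intercept"] = np.ones(n_vol)

    frame = pd.DataFrame(cols).iloc[drop_initial:].reset_index(drop=True)

    # centre nuisance columns and drop the degenerate ones
    dropped: list[str] = []
    for c in list(frame.columns):
        if c.startswith("motion_"):
            frame[c] = frame[c] - frame[c].mean()
            if frame[c].abs().max() < 1e-12:
                frame = frame.drop(columns=c)
                dropped.append(c)
    if dropped:
        log.info("dropped zero-variance nuisance columns: %s", ", ".join(dropped))

    if frame.shape[1] >= len(frame):
        raise ValueError(
            f"design has {frame.shape[1]} columns for {len(frame)} rows"
        )
    _reject_rank_deficiency(frame)
    return DesignMatrix(frame=frame, drop_initial=drop_initial, dropped_columns=tuple(dropped))


def fit_glm(bold: BoldSeries | np.ndarray, design: DesignMatrix, grid: Grid | None = None) -> StatMap:
    """Per-voxel OLS t-map for the task regressor.

    Voxels whose (post-drop) time series have zero variance get t = 0 and
    are counted on the returned map.  Voxels fitted perfectly (zero
    residual with a nonzero task effect) get t = +/-inf, which any finite
    threshold treats as active.
    """
    if isinstance(bold, BoldSeries):
        data, grid = bold.data, bold.grid
    else:
        data = np.asarray(bold, dtype=float)
        if grid is None:
            raise ValueError("grid is required when bold is a bare array")
    X = design.matrix
    n_rows, k = X.shape
    y_full = data.reshape(-1, data.shape[-1])
    if data.shape[-1] == n_rows + design.drop_initial:
        y = y_full[:, design.drop_initial :]
    elif data.shape[-1] == n_rows:
        y = y_full
    else:
        raise ValueError(
            f"BOLD has {data.shape[-1]} volumes; design expects "
            f"{n_rows + design.drop_initial} (pre-drop) or {n_rows} (post-drop)"
        )

    rank = np.linalg.matrix_rank(X)
    dof = n_rows - rank
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T  # (k, n_rows)
    beta = pinv @ y.T  # (k, V)
    resid = y.T - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    c = xtx_inv[design.task_index, design.task_index]
    se = np.sqrt(np.maximum(sigma2 * c, 0.0))

    b_task = beta[design.task_index]
    zero_var = y.var(axis=1) < 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b_task / se
    t[zero_var] = 0.0
    # perfect fit, nonzero effect: infinite t, sign of the effect
    perfect = (~zero_var) & (se == 0.0)
    t[perfect] = np.sign(b_task[perfect]) * np.inf
    t[np.isnan(t)] = 0.0

    n_zero = int(zero_var.sum())
    if n_zero:
        log.info("fit_glm: %d zero-variance voxel series set to t=0", n_zero)
    return StatMap(
        values=t.reshape(data.shape[:3]), grid=grid, dof=int(dof), n_zero_variance=n_zero
    )


_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def smooth(obj, fwhm_mm: float):
    """Gaussian spatial smoothing (sigma = fwhm / 2.355 per axis, in mm).

    Accepts a :class:`BoldSeries` (each volume smoothed, pre-GLM order) or
    a :class:`StatMap`; fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return obj
    if isinstance(obj, BoldSeries):
        sigma_vox = (fwhm_mm / _FWHM_TO_SIGMA) / obj.grid.voxel_sizes
        out = ndimage.gaussian_filter(
            obj.data, sigma=tuple(sigma_vox) + (0.0,), mode="nearest"
        )
        return BoldSeries(data=out, grid=obj.grid, paradigm=obj.paradigm)
    if isinstance(obj, StatMap):
        sigma_vox = (fwhm_mm / _FWHM_TO_SIGMA) / obj.grid.voxel_sizes
        out = ndimage.gaussian_filter(obj.values, sigma=tuple(sigma_vox), mode="nearest")
        return StatMap(values=out, grid=obj.grid, dof=obj.dof, n_zero_variance=obj.n_zero_variance)
    raise TypeError(f"cannot smooth object of type {type(obj).__name__}")


class BlockDesignGLM(BaseEstimator):
    """Estimator wrapper: BOLD series + motion table -> t-statistic map.

    Parameters
    ----------
    paradigm : Paradigm or None
        Block timing. If None, taken from the BoldSeries at fit time.
    drop_initial : int, default 3
        Pre-steady-state volumes discarded from data and design.
    fwhm_mm : float, default 6.0
        Spatial smoothing applied to the series before fitting; 0 disables.
    drift : bool, default True
        Include a linear drift nuisance column.
    """

    def __init__(self, paradigm: Paradigm | None = None, drop_initial: int = 3,
                 fwhm_mm: float = 6.0, drift: bool = True):
        self.paradigm = paradigm
        self.drop_initial = drop_initial
        self.fwhm_mm = fwhm_mm
        self.drift = drift

    def fit(self, bold: BoldSeries, motion: pd.DataFrame | None = None) -> "BlockDesignGLM":
        if not isinstance(bold, BoldSeries):
            raise TypeError("bold must be a BoldSeries")
        paradigm = self.paradigm if self.paradigm is not None else bold.paradigm
        series = smooth(bold, self.fwhm_mm)
        self.design_ = build_design(
            paradigm, motion=motion, drop_initial=self.drop_initial, drift=self.drift
        )
        self.statmap_ = fit_glm(series, self.design_)
        self.dof_ = self.statmap_.dof
        return self

    def transform(self, bold=None) -> StatMap:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "statmap_")
        return self.statmap_

    def fit_transform(self, bold: BoldSeries, motion: pd.DataFrame | None = None) -> StatMap:
        return self.fit(bold, motion=motion).transform()
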