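"""End-to-end orchestration: simulate -> smooth -> GLM -> masks -> LI -> group stats.

A single serializable :class:`RunConfig` drives the whole run; a saved
config plus its seed reproduces every output table.  Each stage logs the
counts that would otherwise be silent (dropped design columns,
zero-variance voxels, undetermined LIs excluded from tests), and the run
manifest records a checksum per written file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm as _glm
from . import group as _group
from .grid import StatMap, default_grid
from .lateralization import DEFAULT_THRESHOLDS, LateralizationSweep, li_curve
from .roi import build_network, default_roi_table, load_roi_table
from .synthetic import CohortSpec, Paradigm, make_paradigm, simulate_cohort, simulate_stat_map

__all__ = ["GroupSpec", "RunConfig", "demo_config", "run_pipeline", "make_fixtures"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: label, task, size and amplitude distributions."""

    name: str
    task: str
    n_subjects: int
    left_amplitude: tuple[float, float]
    right_amplitude: tuple[float, float]


@dataclass(frozen=True)
class RunConfig:
    rest_s: float = 20.0
    task_s: float = 20.0
    cycles: int = 5
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_mm: float = 3.0
    fwhm_mm: float = 6.0
    drop_initial: int = 3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    li_mode: str = "hemispheric"  # or "network"
    roi_table: str | None = None  # JSON path; packaged defaults when None
    noise_sd: float = 0.02
    baseline: float = 1000.0
    motion_sd: float = 0.5
    motion_leak: float = 0.01
    cluster_radius_mm: float = 12.0
    groups: tuple[GroupSpec, ...] = ()
    control_group: str = "control"
    seed: int = 0
    save_tmaps: bool = False

    def validate(self) -> None:
        if not self.thresholds:
            raise ValueError("threshold list must not be empty")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        if not self.groups:
            raise ValueError("config declares no groups")
        if self.li_mode not in ("hemispheric", "network"):
            raise ValueError(f"unknown li_mode '{self.li_mode}'")
        make_paradigm(self.rest_s, self.task_s, self.cycles, self.tr)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["groups"] = tuple(
            GroupSpec(
                name=g["name"], task=g["task"], n_subjects=int(g["n_subjects"]),
                left_amplitude=tuple(g["left_amplitude"]),
                right_amplitude=tuple(g["right_amplitude"]),
            )
            for g in d.get("groups", [])
        )
        for key in ("grid_shape", "thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def demo_config(seed: int = 0) -> RunConfig:
    """Three 10-subject arms: left-only controls, a bilateral (1:1) arm and
    a left-dominant (2:1) arm, on a reduced grid for quick smoke runs."""
    return RunConfig(
        grid_shape=(40, 40, 24),
        fwhm_mm=0.0,
        seed=seed,
        groups=(
            GroupSpec("control", "LWG", 10, (0.03, 0.005), (0.0, 0.0)),
            GroupSpec("tumor", "LWG", 10, (0.03, 0.005), (0.03, 0.005)),
            GroupSpec("vascular", "LWG", 10, (0.03, 0.005), (0.015, 0.0025)),
        ),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write tables + manifest under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paradigm = make_paradigm(config.rest_s, config.task_s, config.cycles, config.tr)
    grid = default_grid(config.grid_shape, config.voxel_mm)
    rois = load_roi_table(config.roi_table) if config.roi_table else default_roi_table()
    masks = build_network(rois if config.li_mode == "network" else None, grid, mode=config.li_mode)
    chash = config.config_hash()

    config.to_json(out / "config.json")

    estimator = _glm.BlockDesignGLM(
        paradigm=paradigm, drop_initial=config.drop_initial, fwhm_mm=config.fwhm_mm
    )

    li_frames = []
    manifests = []
    for gi, gspec in enumerate(config.groups):
        cohort = CohortSpec(
            n_subjects=gspec.n_subjects,
            left_amplitude=tuple(gspec.left_amplitude),
            right_amplitude=tuple(gspec.right_amplitude),
            cluster_centers_mm=tuple(r.center_mm for r in rois),
            cluster_radius_mm=config.cluster_radius_mm,
            noise_sd=config.noise_sd,
            baseline=config.baseline,
            motion_sd=config.motion_sd,
            motion_leak=config.motion_leak,
            grid_shape=config.grid_shape,
            voxel_mm=config.voxel_mm,
            seed=(config.seed * 1009 + gi * 101) % (2**31),
        )
        from .synthetic import cohort_manifest

        man = cohort_manifest(cohort)
        man.insert(0, "group", gspec.name)
        man.insert(1, "task", gspec.task)
        manifests.append(man)
        log.info("group %s: simulating %d subjects", gspec.name, gspec.n_subjects)
        for sub in simulate_cohort(cohort, paradigm):
            tmap = estimator.fit(sub.bold, motion=sub.motion).statmap_
            if config.save_tmaps:
                tmap.to_filename(out / f"tmap_{gspec.name}_{sub.index:03d}.nii")
            curve = li_curve(
                tmap, masks, thresholds=config.thresholds,
                subject=f"{gspec.name}_{sub.index:03d}", group=gspec.name, task=gspec.task,
            )
            li_frames.append(curve.to_frame())

    li_long = pd.concat(li_frames, ignore_index=True)
    li_long["config_hash"] = chash
    li_long["seed"] = config.seed
    li_long.to_csv(out / "li_long.csv", index=False)
    pd.concat(manifests, ignore_index=True).to_csv(out / "cohort_manifest.csv", index=False)

    table = _group.CohortLiTable.from_long(li_long)
    wide = table.frame.copy()
    wide.to_csv(out / "li_wide.csv")

    comp_rows = []
    for gspec in config.groups:
        if gspec.name == config.control_group:
            continue
        try:
            res = _group.group_vs_control_tests(
                table, patient_group=gspec.name, control_group=config.control_group,
                task=gspec.task, control_task=None, base_alpha=config.alpha,
            )
        except ValueError as err:
            log.warning("skipping %s vs control: %s", gspec.name, err)
            continue
        comp_rows += [{"family": "group_vs_control", "group": gspec.name, "task": gspec.task,
                       **dataclasses.asdict(r)} for r in res]
    for gspec in config.groups:
        res = _group.threshold_pair_tests(
            table, group=gspec.name, task=gspec.task, base_alpha=config.alpha
        )
        comp_rows += [{"family": "threshold_pairs", "group": gspec.name, "task": gspec.task,
                       **dataclasses.asdict(r)} for r in res]
    comparisons = pd.DataFrame(comp_rows)
    comparisons["config_hash"] = chash
    comparisons["seed"] = config.seed
    comparisons.to_csv(out / "comparisons.csv", index=False)

    summary = _group.categorize_cohort(table)
    summary["config_hash"] = chash
    summary["seed"] = config.seed
    summary.to_csv(out / "summary.csv", index=False)
    summary.to_json(out / "summary.json", orient="records", indent=1)

    written = sorted(p for p in out.iterdir() if p.is_file())
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects_total": int(sum(g.n_subjects for g in config.groups)),
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the small deterministic fixtures shared across module tests.

    * ``statmap_100_50.nii`` (+ sidecar): 100 left / 50 right active voxels
      at t = 5 on a 16 x 16 x 10 grid — LI = 1/3 at any threshold in (0, 5].
    * ``sphere19.json``: the radius-5 mm sphere case on a 3 mm grid whose
      closed-ball rasterisation holds 19 voxels.
    * ``toy_ttest.csv``: a 4 + 4 sample for the pooled-variance oracle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    grid = default_grid((16, 16, 10), 3.0)
    sm = simulate_stat_map(100, 50, active_t=5.0, inactive_t=0.0, grid=grid, dof=97)
    paths["statmap"] = out / "statmap_100_50.nii"
    sm.to_filename(paths["statmap"])

    paths["sphere"] = out / "sphere19.json"
    paths["sphere"].write_text(json.dumps(
        {"center_mm": [-7.5, 1.5, 1.5], "radius_mm": 5.0,
         "grid_shape": [16, 16, 10], "voxel_mm": 3.0}, indent=1))

    paths["ttest"] = out / "toy_ttest.csv"
    pd.DataFrame(
        {"sample": ["a"] * 4 + ["b"] * 4,
         "value": [0.1, 0.4, 0.35, 0.2, 0.5, 0.7, 0.55, 0.8]}
    ).to_csv(paths["ttest"], index=False)
    return paths
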