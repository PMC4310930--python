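"""Group-level threshold-effect statistics on cohort LI tables.

Two families of comparisons, both pooled-variance (Student) unpaired
two-sample t-tests with dof = n1 + n2 - 2 and Bonferroni-corrected alpha:

* each patient group's LI against the control group, at every threshold
  (alpha / n_thresholds);
* every pair of thresholds within one group and task (alpha / C(k, 2)).

The threshold-pair comparisons are deliberately UNPAIRED even though the
two samples contain the same subjects: published dof bookkeeping of the
form 2n - 2 for n-subject groups identifies the unpaired procedure, and
reproducing that bookkeeping is part of this package's contract.  A
paired variant is available behind ``paired=True`` with the caveat that
it is a different (generally more powerful) procedure.

Undetermined LI entries (empty maps) are removed listwise per comparison
and the exclusion count is carried on the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lateralization import BILATERAL, LEFT, RIGHT, UNDETERMINED, categorize

__all__ = [
    "ComparisonResult",
    "CohortLiTable",
    "two_sample_test",
    "threshold_pair_tests",
    "group_vs_control_tests",
    "bonferroni_alpha",
    "categorize_cohort",
]

_CATEGORY_SYMBOL = {LEFT: "LL", BILATERAL: "B", RIGHT: "RL", UNDETERMINED: "N/A"}


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    t_statistic: float
    dof: int
    p_value: float  # two-tailed
    alpha_corrected: float
    significant: bool
    n_excluded: int = 0
    degenerate: bool = False


def bonferroni_alpha(base_alpha: float, m: int) -> float:
    """Corrected per-comparison alpha: base_alpha / m."""
    if not 0.0 < base_alpha < 1.0:
        raise ValueError(f"base_alpha must lie in (0, 1), got {base_alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return base_alpha / m


def _clean(sample) -> tuple[np.ndarray, int]:
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in np.ravel(np.asarray(sample, dtype=object))]
    )
    kept = arr[~np.isnan(arr)]
    return kept, int(arr.size - kept.size)


def two_sample_test(
    a, b, label: str = "", alpha_corrected: float = 0.05
) -> ComparisonResult:
    """Pooled-variance unpaired two-tailed t-test; dof = n1 + n2 - 2.

    Undefined entries (None/NaN) are removed first.  The degenerate case
    of two zero-variance samples with equal means yields t = 0, p = 1 with
    the ``degenerate`` flag set.
    """
    xa, ex_a = _clean(a)
    xb, ex_b = _clean(b)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(
            f"each sample needs >= 2 defined entries, got {len(xa)} and {len(xb)}"
        )
    dof = len(xa) + len(xb) - 2
    pooled = ((len(xa) - 1) * xa.var(ddof=1) + (len(xb) - 1) * xb.var(ddof=1)) / dof
    degenerate = False
    if pooled == 0.0:
        degenerate = True
        if xa.mean() == xb.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if xa.mean() > xb.mean() else -np.inf
            p = 0.0
    else:
        t_stat, p = stats.ttest_ind(xa, xb, equal_var=True)
        t_stat, p = float(t_stat), float(p)
    return ComparisonResult(
        label=label,
        t_statistic=t_stat,
        dof=dof,
        p_value=p,
        alpha_corrected=alpha_corrected,
        significant=bool(p < alpha_corrected),
        n_excluded=ex_a + ex_b,
        degenerate=degenerate,
    )


class CohortLiTable:
    """Subjects x thresholds LI matrix with group and task labels.

    Wraps a wide DataFrame with index (subject, group, task) and one
    float column per threshold (NaN = undetermined).
    """

    def __init__(self, frame: pd.DataFrame, thresholds: tuple[float, ...]):
        self.thresholds = tuple(float(t) for t in thresholds)
        missing = [t for t in self.thresholds if t not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks threshold columns {missing}")
        self.frame = frame

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CohortLiTable":
        """Build from the long per-subject LI table (the lateralization CSV)."""
        required = {"subject", "group", "task", "threshold", "li"}
        if not required.issubset(long.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        wide = long.pivot_table(
            index=["subject", "group", "task"], columns="threshold", values="li",
            dropna=False,
        )
        thresholds = tuple(sorted(float(c) for c in wide.columns))
        return cls(frame=wide.reset_index().set_index(["subject", "group", "task"]), thresholds=thresholds)

    @classmethod
    def from_curves(cls, curves) -> "CohortLiTable":
        long = pd.concat([c.to_frame() for c in curves], ignore_index=True)
        return cls.from_long(long)

    def subset(self, group: str | None = None, task: str | None = None) -> pd.DataFrame:
        df = self.frame
        idx = df.index.to_frame()
        keep = pd.Series(True, index=df.index)
        if group is not None:
            keep &= idx["group"] == group
        if task is not None:
            keep &= idx["task"] == task
        return df[keep]

    def column(self, threshold: float, group: str | None = None, task: str | None = None) -> np.ndarray:
        return self.subset(group, task)[float(threshold)].to_numpy()


def threshold_pair_tests(
    table: CohortLiTable,
    group: str | None = None,
    task: str | None = None,
    base_alpha: float = 0.05,
    paired: bool = False,
) -> list[ComparisonResult]:
    """All C(k, 2) threshold-pair comparisons within one group/task cell.

    Unpaired pooled-variance tests by default (see module docstring);
    each result carries alpha_corrected = base_alpha / C(k, 2).
    """
    ths = table.thresholds
    if len(ths) < 2:
        raise ValueError("need at least 2 thresholds to compare")
    pairs = list(itertools.combinations(ths, 2))
    alpha_c = bonferroni_alpha(base_alpha, len(pairs))
    results = []
    for t1, t2 in pairs:
        a = table.column(t1, group, task)
        b = table.column(t2, group, task)
        label = f"t<{t1:g} vs. t<{t2:g}"
        if paired:
            mask = ~(np.isnan(a) | np.isnan(b))
            xa, xb = a[mask], b[mask]
            if len(xa) < 2:
                raise ValueError(f"too few paired entries for {label}")
            t_stat, p = stats.ttest_rel(xa, xb)
            results.append(
                ComparisonResult(
                    label=label, t_statistic=float(t_stat), dof=len(xa) - 1,
                    p_value=float(p), alpha_corrected=alpha_c,
                    significant=bool(p < alpha_c),
                    n_excluded=int((~mask).sum()) * 2, degenerate=False,
                )
            )
        else:
            results.append(two_sample_test(a, b, label=label, alpha_corrected=alpha_c))
    return results


def group_vs_control_tests(
    table: CohortLiTable,
    patient_group: str,
    control_group: str = "control",
    task: str | None = None,
    control_task: str | None = None,
    base_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Patient-vs-control comparison of LI at every threshold.

    One unpaired test per threshold; alpha corrected by the number of
    thresholds (0.05 / 4 = 0.0125 for the default sweep).
    """
    alpha_c = bonferroni_alpha(base_alpha, len(table.thresholds))
    results = []
    for tau in table.thresholds:
        a = table.column(tau, group=control_group, task=control_task if control_task is not None else task)
        b = table.column(tau, group=patient_group, task=task)
        results.append(
            two_sample_test(
                a, b, label=f"{control_group} vs. {patient_group} @ t<{tau:g}",
                alpha_corrected=alpha_c,
            )
        )
    return results


def categorize_cohort(table: CohortLiTable) -> pd.DataFrame:
    """Category-of-mean-LI per (group, task, threshold) plus the
    lowest-to-highest-threshold transition string.

    Transition strings follow the 'B -> LL' convention (B bilateral, LL
    left-lateralized, RL right-lateralized); identical endpoint
    categories yield e.g. 'B (no change)'; an empty cell yields 'N/A'.
    """
    if len(table.frame) == 0:
        raise ValueError("empty cohort table")
    rows = []
    idx = table.frame.index.to_frame(index=False)
    for (grp, task), _ in table.frame.groupby(["group", "task"], sort=True):
        cell = table.subset(group=grp, task=task)
        row: dict = {"group": grp, "task": task, "n": len(cell)}
        cats = {}
        for tau in table.thresholds:
            vals = cell[float(tau)].dropna()
            mean_li = float(vals.mean()) if len(vals) else None
            cat = categorize(mean_li)
            cats[tau] = cat
            row[f"mean_li_t{tau:g}"] = np.nan if mean_li is None else mean_li
            row[f"category_t{tau:g}"] = cat
        lo = _CATEGORY_SYMBOL[cats[table.thresholds[0]]]
        hi = _CATEGORY_SYMBOL[cats[table.thresholds[-1]]]
        if lo == "N/A" or hi == "N/A":
            row["transition"] = "N/A"
        elif lo == hi:
            row["transition"] = f"{lo} (no change)"
        else:
            row["transition"] = f"{lo} → {hi}"
        rows.append(row)
    return pd.DataFrame(rows)
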