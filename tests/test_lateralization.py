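"""The LI statistic: counting, the exact ratio, categories, threshold sweeps."""

from fractions import Fraction

import numpy as np
import pytest

from lisweep import (
    RoiSpec,
    build_network,
    categorize,
    compute_li,
    count_active,
    default_grid,
    li_curve,
    roi_pair_lis,
    simulate_stat_map,
    sphere_mask,
)
from lisweep.grid import StatMap
from lisweep.lateralization import LateralizationSweep


@pytest.fixture(scope="module")
def hemi_masks(small_grid):
    return build_network(None, small_grid, mode="hemispheric")


class TestCountActive:
    def test_constructed_counts_recovered(self, small_grid, hemi_masks):
        sm = simulate_stat_map(100, 50, active_t=5.0, inactive_t=0.0, grid=small_grid)
        assert count_active(sm, hemi_masks.left, 2.0) == 100
        assert count_active(sm, hemi_masks.right, 2.0) == 50

    def test_threshold_above_global_max_counts_zero(self, small_grid, hemi_masks):
        sm = simulate_stat_map(100, 50, active_t=5.0, grid=small_grid)
        assert count_active(sm, hemi_masks.left, 5.1) == 0

    def test_threshold_equal_to_t_is_inclusive(self, small_grid, hemi_masks):
        sm = simulate_stat_map(100, 50, active_t=5.0, grid=small_grid)
        assert count_active(sm, hemi_masks.left, 5.0) == 100

    def test_two_sided_counts_negative_tail(self, small_grid, hemi_masks):
        vals = np.zeros(small_grid.shape)
        vals[hemi_masks.left] = -6.0
        sm = StatMap(values=vals, grid=small_grid, dof=50)
        assert count_active(sm, hemi_masks.left, 2.0) == 0
        assert count_active(sm, hemi_masks.left, 2.0, two_sided=True) == int(
            hemi_masks.left.sum()
        )

    def test_grid_mismatch_rejected(self, small_grid):
        sm = simulate_stat_map(1, 1, active_t=5.0, grid=small_grid)
        with pytest.raises(ValueError, match="shape"):
            count_active(sm, np.ones((2, 2, 2), dtype=bool), 2.0)


class TestComputeLi:
    def test_direct_formula(self):
        assert compute_li(100, 50) == pytest.approx(1 / 3)
        assert compute_li(100, 50) == float(Fraction(50, 150))

    def test_empty_counts_are_undefined_not_zero(self):
        assert compute_li(0, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_li(-1, 5)

    def test_antisymmetry_exhaustive_to_50(self):
        for a in range(51):
            for b in range(51):
                if a + b == 0:
                    continue
                assert compute_li(a, b) == -compute_li(b, a)

    def test_bounds(self):
        assert compute_li(7, 0) == 1.0
        assert compute_li(0, 7) == -1.0
        assert compute_li(7, 7) == 0.0


class TestCategorize:
    @pytest.mark.parametrize(
        "li,expected",
        [
            (1 / 3, "left"),
            (0.2, "bilateral"),  # boundary belongs to bilateral
            (-0.2, "bilateral"),
            (0.2000001, "left"),
            (-0.21, "right"),
            (1.0, "left"),  # endpoint: maximally left-dominant
            (-1.0, "right"),
            (None, "undetermined"),
        ],
    )
    def test_scale(self, li, expected):
        assert categorize(li) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(1.5)


class TestLiCurve:
    def test_left_only_map_is_left_at_every_threshold(self, small_grid, hemi_masks):
        sm = simulate_stat_map(40, 0, active_t=10.0, grid=small_grid)
        curve = li_curve(sm, hemi_masks)
        assert [r.li for r in curve.records] == [1.0] * 4
        assert {r.category for r in curve.records} == {"left"}

    def test_bilateral_to_left_crossing(self, small_grid, hemi_masks):
        """Equal counts at low threshold, left-only survival at high."""
        vals = np.zeros(small_grid.shape)
        left_idx = np.flatnonzero(hemi_masks.left.ravel())[:30]
        right_idx = np.flatnonzero(hemi_masks.right.ravel())[:30]
        vals.ravel()[left_idx] = 5.0
        vals.ravel()[right_idx] = 3.0
        sm = StatMap(values=vals, grid=small_grid, dof=90)
        curve = li_curve(sm, hemi_masks, thresholds=(2.0, 4.0))
        assert curve.records[0].li == 0.0
        assert curve.records[0].category == "bilateral"
        assert curve.records[1].li == 1.0
        assert curve.records[1].category == "left"

    def test_single_threshold_matches_direct_calls(self, small_grid, hemi_masks):
        sm = simulate_stat_map(17, 5, active_t=5.0, grid=small_grid)
        curve = li_curve(sm, hemi_masks, thresholds=[2.0])
        vl = count_active(sm, hemi_masks.left, 2.0)
        vr = count_active(sm, hemi_masks.right, 2.0)
        assert (curve.records[0].v_left, curve.records[0].v_right) == (vl, vr)
        assert curve.records[0].li == compute_li(vl, vr)

    def test_counts_monotone_in_threshold(self, small_grid, hemi_masks):
        rng = np.random.default_rng(0)
        sm = StatMap(values=rng.standard_normal(small_grid.shape) * 3, grid=small_grid, dof=90)
        curve = li_curve(sm, hemi_masks)
        vls = [r.v_left for r in curve.records]
        vrs = [r.v_right for r in curve.records]
        assert vls == sorted(vls, reverse=True)
        assert vrs == sorted(vrs, reverse=True)

    def test_empty_map_is_undetermined(self, small_grid, hemi_masks):
        sm = StatMap(values=np.zeros(small_grid.shape), grid=small_grid, dof=90)
        curve = li_curve(sm, hemi_masks)
        assert {r.category for r in curve.records} == {"undetermined"}
        assert all(r.li is None for r in curve.records)

    def test_bad_threshold_lists_rejected(self, small_grid, hemi_masks):
        sm = simulate_stat_map(1, 1, active_t=5.0, grid=small_grid)
        with pytest.raises(ValueError, match="non-empty"):
            li_curve(sm, hemi_masks, thresholds=[])
        with pytest.raises(ValueError, match="increasing"):
            li_curve(sm, hemi_masks, thresholds=[3.0, 2.0])

    def test_mirror_antisymmetry_exact(self, small_grid, hemi_masks):
        """LI of the x-mirrored map is exactly -LI of the original."""
        rng = np.random.default_rng(4)
        sm = StatMap(values=rng.standard_normal(small_grid.shape) * 3, grid=small_grid, dof=90)
        orig = li_curve(sm, hemi_masks)
        mirr = li_curve(sm.mirrored(), hemi_masks)
        for a, b in zip(orig.records, mirr.records):
            if a.li is None:
                assert b.li is None
            else:
                assert b.li == -a.li


class TestRoiPairLis:
    def test_mean_over_defined_pairs(self, small_grid):
        pair_a = RoiSpec("a", (-7.5, 4.5, 1.5), 4.0)
        pair_b = RoiSpec("b", (-7.5, -4.5, 1.5), 4.0)
        vals = np.zeros(small_grid.shape)
        vals[sphere_mask(pair_a.center_mm, 4.0, small_grid)] = 5.0  # left-only: li 1
        vals[sphere_mask(pair_b.center_mm, 4.0, small_grid)] = 5.0  # both sides: li 0
        vals[sphere_mask((7.5, -4.5, 1.5), 4.0, small_grid)] = 5.0
        sm = StatMap(values=vals, grid=small_grid, dof=90)
        records, mean_li = roi_pair_lis(sm, [pair_a, pair_b], threshold=2.0)
        assert [r.li for r in records] == [1.0, 0.0]
        assert mean_li == pytest.approx(0.5)

    def test_all_pairs_empty_mean_undefined(self, small_grid):
        sm = StatMap(values=np.zeros(small_grid.shape), grid=small_grid, dof=90)
        records, mean_li = roi_pair_lis(
            sm, [RoiSpec("a", (-7.5, 4.5, 1.5), 4.0)], threshold=2.0
        )
        assert mean_li is None
        assert records[0].category == "undetermined"

    def test_mean_matches_brute_force_recount(self, small_grid):
        rng = np.random.default_rng(5)
        sm = StatMap(values=rng.standard_normal(small_grid.shape) * 3, grid=small_grid, dof=90)
        rois = [RoiSpec("a", (-7.5, 4.5, 1.5), 5.0), RoiSpec("b", (-10.5, -4.5, -1.5), 5.0)]
        records, mean_li = roi_pair_lis(sm, rois, threshold=1.0)
        oracle = []
        for r in rois:
            lm = sphere_mask(r.center_mm, r.radius_mm, small_grid)
            rm = sphere_mask((-r.center_mm[0],) + r.center_mm[1:], r.radius_mm, small_grid)
            vl = int((lm & (sm.values >= 1.0)).sum())
            vr = int((rm & (sm.values >= 1.0)).sum())
            if vl + vr:
                oracle.append((vl - vr) / (vl + vr))
        assert mean_li == pytest.approx(np.mean(oracle))


class TestLateralizationSweepEstimator:
    def test_transform_matches_li_curve(self, small_grid):
        sweep = LateralizationSweep(mode="hemispheric")
        maps = [
            simulate_stat_map(40, 10, active_t=5.0, grid=small_grid),
            simulate_stat_map(5, 25, active_t=5.0, grid=small_grid),
        ]
        frame = sweep.fit(maps).transform(maps)
        assert len(frame) == 8  # 2 maps x 4 thresholds
        first = frame[(frame.subject == 0) & (frame.threshold == 2.0)].iloc[0]
        assert first.v_left == 40 and first.v_right == 10
        assert first.li == pytest.approx(30 / 50)
        second = frame[(frame.subject == 1) & (frame.threshold == 2.0)].iloc[0]
        assert second.category == "right"

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        sweep = LateralizationSweep(thresholds=(1.0, 2.0), mode="network")
        assert clone(sweep).get_params()["thresholds"] == (1.0, 2.0)
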