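import numpy as np
import pytest

from buteo_abm import (
    Buzzard,
    RunConfig,
    StudyMask,
    abundance,
    core_profile,
    occupancy_raster,
    pairwise_overlaps,
    percentage_polygon,
    run_simulation,
)
from buteo_abm.landscape import InvalidInputError
from buteo_abm.ranges import DEFAULT_LEVELS, RangeCore
from shapely.geometry import Polygon


def square(x0, y0, side):
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


def core_from(poly, bird_id, level=80.0):
    return RangeCore(bird_id=bird_id, level=level, polygon=poly,
                     area_ha=poly.area / 10_000.0, perimeter_m=poly.exterior.length)


class TestPercentagePolygon:
    def test_unit_square_full_level(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        core = percentage_polygon(pts, 100)
        assert core.polygon.area == pytest.approx(1.0)
        assert core.perimeter_m == pytest.approx(4.0)

    def test_outliers_peeled_at_80(self):
        rng = np.random.default_rng(0)
        cluster = rng.uniform(0, 10, size=(8, 2))
        outliers = np.array([[500.0, 500.0], [-400.0, 300.0]])
        pts = np.vstack([cluster, outliers])
        core = percentage_polygon(pts, 80)
        # ceil(0.8*10)=8 nearest the mean centre: exactly the cluster
        from shapely.geometry import MultiPoint

        assert core.polygon.equals(MultiPoint(cluster).convex_hull)

    def test_single_point_zero_area(self):
        core = percentage_polygon(np.array([[3.0, 4.0]]), 50)
        assert core.area_ha == 0.0
        assert core.perimeter_m == 0.0

    def test_collinear_points_zero_area_defined_perimeter(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        core = percentage_polygon(pts, 100)
        assert core.area_ha == 0.0
        assert core.perimeter_m == pytest.approx(40.0)  # out-and-back

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            percentage_polygon(np.empty((0, 2)), 80)
        with pytest.raises(InvalidInputError):
            percentage_polygon(np.array([[0.0, 0.0]]), 0)


class TestCoreProfile:
    def _bird(self, n=40, seed=1):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 200, size=(n, 2))
        return Buzzard(name=0, my_roost=(0, 0), X=pts[:, 0].tolist(), Y=pts[:, 1].tolist())

    def test_default_levels_count(self):
        assert len(DEFAULT_LEVELS) == 11
        profile = core_profile(self._bird())
        assert len(profile) == 11
        assert [c.level for c in profile] == list(range(30, 85, 5))

    def test_one_pixel_territory_zero_area(self):
        bird = Buzzard(name=0, my_roost=(0, 0), X=[12.5], Y=[12.5])
        assert all(c.area_ha == 0 for c in core_profile(bird))

    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_areas_non_decreasing(self, seed):
        profile = core_profile(self._bird(seed=seed))
        areas = [c.area_ha for c in profile]
        perims = [c.perimeter_m for c in profile]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(areas, areas[1:]))
        assert all(p2 >= p1 - 1e-9 for p1, p2 in zip(perims, perims[1:]))

    @pytest.mark.parametrize("seed", range(3))
    def test_higher_level_polygon_contains_lower(self, seed):
        profile = core_profile(self._bird(seed=100 + seed))
        for lo, hi in zip(profile, profile[1:]):
            assert hi.polygon.buffer(1e-9).contains(lo.polygon)


class TestPairwiseOverlaps:
    def test_identical_squares_both_100(self):
        a, b = core_from(square(0, 0, 100), 0), core_from(square(0, 0, 100), 1)
        recs = pairwise_overlaps([a, b])
        assert len(recs) == 2
        assert all(r.overlap_pct == pytest.approx(100.0) for r in recs)

    def test_disjoint_squares_no_records(self):
        recs = pairwise_overlaps([core_from(square(0, 0, 10), 0), core_from(square(100, 100, 10), 1)])
        assert recs == []

    def test_half_overlap_ordered(self):
        a = core_from(square(0, 0, 100), 0)           # unit square (100 m)
        b = core_from(square(50, 0, 50), 1)           # covers right half, half height
        recs = {(r.bird_a, r.bird_b): r.overlap_pct for r in pairwise_overlaps([a, b])}
        assert recs[(0, 1)] == pytest.approx(25.0)    # b covers 1/4 of a
        assert recs[(1, 0)] == pytest.approx(100.0)   # a covers all of b

    def test_intersection_symmetric_percentages_not(self):
        a = core_from(square(0, 0, 100), 0)
        b = core_from(square(50, 0, 100), 1)
        recs = {(r.bird_a, r.bird_b): r.overlap_pct for r in pairwise_overlaps([a, b])}
        assert recs[(0, 1)] == pytest.approx(recs[(1, 0)])  # equal areas here
        c = core_from(square(50, 0, 50), 2)
        recs2 = {(r.bird_a, r.bird_b): r.overlap_pct for r in pairwise_overlaps([a, c])}
        assert recs2[(0, 2)] * a.area_ha == pytest.approx(recs2[(2, 0)] * c.area_ha)

    def test_symmetric_flag_single_record(self):
        a = core_from(square(0, 0, 100), 0)
        b = core_from(square(50, 0, 100), 1)
        recs = pairwise_overlaps([a, b], symmetric=True)
        assert len(recs) == 1
        assert recs[0].overlap_pct == pytest.approx(100 * 5000 / 15000)

    def test_mixed_levels_rejected(self):
        a = core_from(square(0, 0, 1), 0, level=40)
        b = core_from(square(0, 0, 1), 1, level=80)
        with pytest.raises(InvalidInputError):
            pairwise_overlaps([a, b])


class TestAbundanceAndOccupancy:
    def test_all_in_core(self, three_kit_map):
        res = run_simulation(three_kit_map, None, config=RunConfig(seed=0))
        mask = StudyMask(core=np.ones(three_kit_map.grid.shape, dtype=bool))
        assert abundance(res, mask) == 3

    def test_strip_roost_excluded_but_blocks(self, three_kit_map):
        res = run_simulation(three_kit_map, None, config=RunConfig(seed=0))
        core = np.ones(three_kit_map.grid.shape, dtype=bool)
        excluded = res.buzzards[0]
        core[excluded.my_roost[1], excluded.my_roost[0]] = False
        assert abundance(res, StudyMask(core=core)) == 2
        occ = occupancy_raster(res)  # territory still blocks pixels
        assert (occ.owners == excluded.name).sum() == len(excluded.territory_pixels)

    def test_empty_result_zero(self, three_kit_map):
        from buteo_abm import SimulationParams, SimulationResult
        from buteo_abm.engine import WorldState

        res = SimulationResult([], WorldState(three_kit_map), 0, 0, SimulationParams())
        mask = StudyMask(core=np.ones(three_kit_map.grid.shape, dtype=bool))
        assert abundance(res, mask) == 0

    def test_occupancy_conserves_defended_pixels(self, three_kit_map):
        res = run_simulation(three_kit_map, None, config=RunConfig(seed=2))
        occ = occupancy_raster(res)
        total = sum(len(b.territory_pixels) for b in res.buzzards)
        assert (occ.owners != -1).sum() == total
        assert occ.roosts.sum() == len(res.buzzards)
        for b in res.buzzards:
            rows_cols = np.nonzero(occ.owners == b.name)
            got = set(zip(rows_cols[1].tolist(), rows_cols[0].tolist()))
            assert got == b.territory_pixels
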