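import numpy as np
import pytest

from buteo_abm import (
    CategoryMapping,
    Resource,
    ResourceMap,
    label_patches,
    make_study_mask,
    translate_landcover,
)
from buteo_abm.landscape import InvalidInputError, full_mask


class TestResourceMap:
    def test_extents_and_pixel_area(self):
        m = ResourceMap(np.zeros((240, 880), dtype=np.int8), pixel_size=25.0)
        assert m.map_eastings == 880 * 25
        assert m.map_northings == 240 * 25
        assert m.pixel_area_ha == pytest.approx(0.0625)

    def test_rejects_empty_and_invalid_codes(self):
        with pytest.raises(InvalidInputError):
            ResourceMap(np.zeros((0, 5), dtype=np.int8))
        with pytest.raises(InvalidInputError):
            ResourceMap(np.full((3, 3), 9, dtype=np.int8))

    def test_pixel_centres_row0_is_north(self):
        m = ResourceMap(np.zeros((2, 2), dtype=np.int8), pixel_size=25.0, origin=(100.0, 200.0))
        assert m.pixel_centre(0, 0) == (112.5, 237.5)  # top-left pixel is northernmost
        assert m.pixel_centre(1, 1) == (137.5, 212.5)


class TestTranslate:
    def test_lookup_with_default(self):
        mapping = CategoryMapping({1: Resource.WOODLAND, 2: Resource.MEADOW})
        out = translate_landcover(np.array([[1, 2], [3, 1]]), mapping)
        expected = np.array(
            [[Resource.WOODLAND, Resource.MEADOW], [Resource.OTHER, Resource.WOODLAND]]
        )
        np.testing.assert_array_equal(out.grid, expected)

    def test_identity_all_woodland(self):
        mapping = CategoryMapping({5: Resource.WOODLAND})
        out = translate_landcover(np.full((10, 10), 5), mapping)
        assert out.counts()[Resource.WOODLAND] == 100
        assert sum(v for k, v in out.counts().items() if k != Resource.WOODLAND) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conserves_class_counts(self, seed):
        """Multiset of output codes equals the mapping image of input IDs."""
        rng = np.random.default_rng(seed)
        ids = rng.integers(0, 12, size=(31, 17))
        mapping = CategoryMapping(
            {1: Resource.WOODLAND, 2: Resource.MEADOW, 3: Resource.ROUGH, 7: Resource.WATER}
        )
        out = translate_landcover(ids, mapping)
        for res in Resource:
            brute = sum(
                int(np.count_nonzero(ids == cat))
                for cat in range(13)
                if mapping[cat] == res
            )
            assert out.counts()[res] == brute

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            translate_landcover(np.empty((0, 0)), CategoryMapping())


class TestLabelPatches:
    def _map_with(self, pixels, code=Resource.MEADOW, shape=(8, 8)):
        grid = np.zeros(shape, dtype=np.int8)
        for c, r in pixels:
            grid[r, c] = int(code)
        return ResourceMap(grid, pixel_size=25.0)

    def test_diagonal_connectivity(self):
        m = self._map_with([(2, 2), (3, 3)])
        assert len(label_patches(m, Resource.MEADOW, connectivity=4)) == 2
        assert len(label_patches(m, Resource.MEADOW, connectivity=8)) == 1

    def test_plus_shape_area(self):
        m = self._map_with([(3, 3), (2, 3), (4, 3), (3, 2), (3, 4)], code=Resource.ROUGH)
        patches = label_patches(m, Resource.ROUGH)
        assert len(patches) == 1
        assert patches[0].area_ha == pytest.approx(5 * 0.0625)
        assert patches[0].pixels == {(3, 3), (2, 3), (4, 3), (3, 2), (3, 4)}

    def test_absent_resource_empty(self):
        m = self._map_with([])
        assert label_patches(m, Resource.WOODLAND) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_property(self, connectivity, stochastic_map):
        """Patches partition the resource pixels and never touch each other."""
        patches = label_patches(stochastic_map, Resource.MEADOW, connectivity)
        all_px = [p for patch in patches for p in patch.pixels]
        assert len(all_px) == len(set(all_px))  # pairwise disjoint
        rows, cols = np.nonzero(stochastic_map.grid == int(Resource.MEADOW))
        assert set(all_px) == set(zip(cols.tolist(), rows.tolist()))
        total = sum(p.area_ha for p in patches)
        assert total == pytest.approx(len(all_px) * stochastic_map.pixel_area_ha)


class TestStudyMask:
    def test_core_pixel_count(self):
        m = ResourceMap(np.zeros((400, 1000), dtype=np.int8), pixel_size=25.0)
        mask = make_study_mask(m, (1000.0, 1000.0, 23_000.0, 7_000.0), strip_width=1000.0)
        assert mask.core.sum() == 880 * 240
        assert mask.strip_width == 1000.0

    def test_full_world_core(self):
        m = ResourceMap(np.zeros((10, 10), dtype=np.int8), pixel_size=25.0)
        mask = make_study_mask(m, (0.0, 0.0, 250.0, 250.0), strip_width=0.0)
        assert mask.core.all()
        assert np.array_equal(mask.core, full_mask(m).core)

    def test_core_outside_world_rejected(self):
        m = ResourceMap(np.zeros((10, 10), dtype=np.int8), pixel_size=25.0)
        with pytest.raises(InvalidInputError):
            make_study_mask(m, (0.0, 0.0, 300.0, 100.0), strip_width=0.0)
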