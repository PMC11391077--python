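"""Fragment labelling vs a flood-fill oracle, areas, and report rules."""

import numpy as np
import pytest

import biomefusion as bf
from biomefusion.fragmentation import biome_mask, fragment_report, label_fragments
from biomefusion.grid import EARTH_RADIUS_KM
from biomefusion.scheme import BiomeMap


def flood_fill_components(mask):
    """Brute-force 4-connected component labelling (independent oracle)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            r, c = stack.pop()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                    if mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = current
                        stack.append((rr, cc))
    return labels, current


def geom(n_lat, n_lon, res=1.0):
    return bf.GridGeometry(
        lon_min=0, lon_max=n_lon * res, lat_min=0, lat_max=n_lat * res, resolution=res
    )


def uniform_map(mask, codes=("A", "B")):
    """BiomeMap with code A where mask, B elsewhere, on a uniform-area-ish grid."""
    g = geom(*mask.shape, res=0.1)  # near-equator small cells: nearly uniform areas
    arr = np.where(mask, 0, 1).astype(np.int16)
    return BiomeMap(geometry=g, codes=arr, scheme_codes=list(codes))


class TestCellArea:
    def test_equatorial_half_degree_cell(self):
        g = bf.GridGeometry(lon_min=0, lon_max=10, lat_min=-0.25, lat_max=9.75, resolution=0.5)
        area = g.cell_area_km2(0)  # spans the equator symmetrically
        expected = EARTH_RADIUS_KM**2 * np.deg2rad(0.5) * 2 * np.sin(np.deg2rad(0.25))
        assert area == pytest.approx(expected)
        assert area == pytest.approx(3091.07, abs=0.05)

    def test_cosine_weighting_at_60_degrees(self):
        g = bf.GridGeometry(lon_min=0, lon_max=10, lat_min=-0.25, lat_max=89.75, resolution=0.5)
        eq = g.cell_area_km2(0)
        at60 = g.cell_area_km2(g.cell_of(0.1, 60.0)[0])
        assert at60 / eq == pytest.approx(0.5, rel=2e-3)

    def test_global_grid_sums_to_sphere_area(self):
        g = bf.GridGeometry(lon_min=-180, lon_max=180, lat_min=-90, lat_max=90, resolution=2.0)
        total = g.cell_areas().sum()
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_KM**2, rel=1e-6)


class TestLabelFragments:
    def test_diagonal_cells_are_separate(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        _, areas = label_fragments(mask, geom(4, 4))
        assert len(areas) == 2

    def test_full_mask_is_one_fragment(self):
        g = geom(5, 7)
        labels, areas = label_fragments(np.ones((5, 7), bool), g)
        assert len(areas) == 1
        assert areas[0] == pytest.approx(g.cell_areas().sum())

    def test_empty_mask(self):
        _, areas = label_fragments(np.zeros((3, 3), bool), geom(3, 3))
        assert len(areas) == 0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_flood_fill_oracle_on_random_masks(self, trial):
        rng = np.random.default_rng(1000 + trial)
        mask = rng.random((30, 30)) < rng.uniform(0.2, 0.8)
        g = geom(30, 30)
        labels, areas = label_fragments(mask, g)
        oracle_labels, oracle_n = flood_fill_components(mask)
        assert len(areas) == oracle_n
        # identical partitions up to label permutation
        for k in range(1, oracle_n + 1):
            ours = labels[oracle_labels == k]
            assert len(np.unique(ours)) == 1 and ours[0] > 0
        np.testing.assert_allclose(np.sort(areas), np.sort(
            [g.cell_areas()[oracle_labels == k].sum() for k in range(1, oracle_n + 1)]
        ))

    def test_area_conservation(self):
        rng = np.random.default_rng(9)
        mask = rng.random((25, 40)) < 0.5
        g = geom(25, 40, res=0.5)
        _, areas = label_fragments(mask, g)
        assert areas.sum() == pytest.approx(g.cell_areas()[mask].sum(), rel=1e-9)


class TestBiomeMask:
    def test_union_identity(self, scheme, small_geometry):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, len(scheme.codes), small_geometry.shape).astype(np.int16)
        bmap = BiomeMap(geometry=small_geometry, codes=codes, scheme_codes=scheme.codes)
        m_thf = biome_mask(bmap, ["Thf"])
        m_wts = biome_mask(bmap, ["WTs"])
        np.testing.assert_array_equal(biome_mask(bmap, ["Thf", "WTs"]), m_thf | m_wts)

    def test_all_codes_equals_land(self, scheme, small_geometry):
        codes = np.zeros(small_geometry.shape, np.int16)
        codes[0, 0] = -1
        bmap = BiomeMap(geometry=small_geometry, codes=codes, scheme_codes=scheme.codes)
        np.testing.assert_array_equal(biome_mask(bmap, scheme.codes), codes >= 0)

    def test_empty_code_set_rejected(self, scheme, small_geometry):
        bmap = BiomeMap(
            geometry=small_geometry,
            codes=np.zeros(small_geometry.shape, np.int16),
            scheme_codes=scheme.codes,
        )
        with pytest.raises(Exception):
            biome_mask(bmap, [])

    def test_union_fragments_contain_single_code_fragments(self, scheme):
        """Every fragment of mask(A) lies inside exactly one fragment of mask(A|B)."""
        rng = np.random.default_rng(12)
        codes = rng.integers(0, 3, (20, 20)).astype(np.int16)
        bmap = BiomeMap(geometry=geom(20, 20), codes=codes, scheme_codes=["A", "B", "C"])
        la, _ = label_fragments(biome_mask(bmap, ["A"]), bmap.geometry)
        lab, _ = label_fragments(biome_mask(bmap, ["A", "B"]), bmap.geometry)
        for k in range(1, la.max() + 1):
            containers = np.unique(lab[la == k])
            assert len(containers) == 1 and containers[0] > 0


class TestFragmentReport:
    def test_hand_computed_12_plus_1(self):
        """Fragments of 12 and 1 cells: 1 major, 2 total, 7.69% outside main."""
        mask = np.zeros((5, 15), bool)
        mask[2, 0:12] = True
        mask[0, 14] = True
        rep = fragment_report(uniform_map(mask), ["A"])
        assert rep.n_total_fragments == 2
        assert rep.n_major_fragments == 1  # 1 cell < 10% of 12 cells
        assert rep.pct_outside_main == pytest.approx(100 * 1 / 13, rel=1e-3)

    def test_ten_percent_boundary_inclusive(self):
        """Fragments of 10 and 1 cells: the 1-cell fragment is exactly 10% -> major."""
        mask = np.zeros((5, 13), bool)
        mask[2, 0:10] = True
        mask[0, 12] = True
        rep = fragment_report(uniform_map(mask), ["A"], cell_count_areas=True)
        assert rep.n_major_fragments == 2

    def test_single_fragment_zero_outside(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        rep = fragment_report(uniform_map(mask), ["A"])
        assert rep.n_total_fragments == 1
        assert rep.pct_outside_main == 0.0

    def test_empty_set_reports_zeros_with_flag(self):
        rep = fragment_report(uniform_map(np.zeros((3, 3), bool)), ["A"])
        assert rep.empty
        assert rep.n_total_fragments == 0 and rep.pct_outside_main == 0.0

    def test_areas_sum_to_total(self):
        rng = np.random.default_rng(2)
        mask = rng.random((15, 15)) < 0.5
        rep = fragment_report(uniform_map(mask), ["A"])
        assert sum(rep.fragment_areas_km2) == pytest.approx(rep.total_area_km2, rel=1e-9)
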