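import numpy as np
import pytest
import shapely
from scipy import ndimage

from tmespat.caa import (
    Aggregate,
    CAAConfig,
    GridCounts,
    aggregates_to_polygons,
    cells_in_region,
    delineate_aggregates,
    grid_counts,
    grow_aggregates,
    infiltration_areas,
    region_mask,
    seed_squares,
)
from tmespat.errors import DataError
from tmespat.io import FOVWindow
from tmespat.phenotype import assign_phenotypes

from conftest import make_cells


def grid_from_counts(counts, label="Tumor", s=10.0, fov="F1"):
    counts = np.asarray(counts, dtype=int)
    return GridCounts(fov, 0.0, 0.0, s, counts.shape[0], counts.shape[1], {label: counts})


def oracle_components(counts, seeds, cutoff, connectivity):
    """Independent oracle: connected components (scipy.ndimage labeling) of
    {count >= cutoff} ∪ seeds that contain at least one seed."""
    mask = np.asarray(counts) >= cutoff
    for r, c in seeds:
        mask[r, c] = True
    structure = np.ones((3, 3)) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    lab, n = ndimage.label(mask, structure=structure)
    seed_labels = {lab[r, c] for r, c in seeds}
    out = []
    for k in sorted(seed_labels):
        rows, cols = np.where(lab == k)
        out.append(frozenset(zip(rows.tolist(), cols.tolist())))
    return set(out)


class TestGridCounts:
    def make_table(self, xy, label="Tumor"):
        t = make_cells({"x": [p[0] for p in xy], "y": [p[1] for p in xy], "S100": 100.0,
                        "CD3": 5.0, "CD20": 5.0, "CD8": 5.0, "PD1": 5.0, "CD4": 5.0, "FOXP3": 5.0,
                        "HLA1": 5.0},
                       markers=("S100", "HLA1", "CD3", "CD20", "CD8", "PD1", "CD4", "FOXP3"))
        return assign_phenotypes(t)

    def test_window_subdivision(self):
        t = self.make_table([(10, 10)])
        w = FOVWindow("F1", 0, 100, 0, 100)
        g = grid_counts(t, w, CAAConfig(square_size_um=50), ["Tumor"])
        assert (g.n_rows, g.n_cols) == (2, 2)

    def test_interior_edge_goes_right_upper(self):
        t = self.make_table([(50.0, 50.0)])
        g = grid_counts(t, FOVWindow("F1", 0, 100, 0, 100), CAAConfig(square_size_um=50), ["Tumor"])
        assert g.counts["Tumor"][1, 1] == 1 and g.counts["Tumor"].sum() == 1

    def test_counts_sum_to_class_cells(self):
        xy = [(12.0, 7.0)] * 5
        g = grid_counts(self.make_table(xy), FOVWindow("F1", 0, 100, 0, 100), CAAConfig(square_size_um=50), ["Tumor"])
        assert g.counts["Tumor"][0, 0] == 5 and g.counts["Tumor"].sum() == 5

    def test_far_edge_cell_kept(self):
        g = grid_counts(self.make_table([(100.0, 100.0)]), FOVWindow("F1", 0, 100, 0, 100),
                        CAAConfig(square_size_um=50), ["Tumor"])
        assert g.counts["Tumor"][1, 1] == 1

    def test_empty_class_zero_matrix(self):
        g = grid_counts(self.make_table([(1.0, 1.0)]), FOVWindow("F1", 0, 100, 0, 100),
                        CAAConfig(square_size_um=50), ["Tumor", "CD3"])
        assert g.counts["CD3"].sum() == 0


class TestSeedSquares:
    def test_single_hot_square_among_zeros(self):
        counts = np.zeros((10, 10), dtype=int)
        counts[3, 7] = 10
        g = grid_from_counts(counts)
        # P95 of 99 zeros and one 10 is 0 -> only the hot square is above it
        assert seed_squares(g, "Tumor", CAAConfig(seed_percentile=95)) == {(3, 7)}

    def test_uniform_counts_no_seeds(self):
        g = grid_from_counts(np.full((5, 5), 4))
        assert seed_squares(g, "Tumor", CAAConfig()) == set()

    def test_interpolated_quantile_on_1_to_100(self):
        counts = np.arange(1, 101).reshape(10, 10)
        g = grid_from_counts(counts)
        seeds = seed_squares(g, "Tumor", CAAConfig(seed_percentile=95))
        # sorted values 1..100: P95 by linear interpolation = 95.05
        # -> seeds are exactly the squares counting 96..100
        expect = {tuple(map(int, np.argwhere(counts == v)[0])) for v in (96, 97, 98, 99, 100)}
        assert seeds == expect


class TestGrowAggregates:
    def test_isolated_seed_stops_immediately(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[2, 2] = 9
        g = grid_from_counts(counts)
        aggs = grow_aggregates(g, "Tumor", {(2, 2)}, CAAConfig(growth_cutoff=5))
        assert len(aggs) == 1 and aggs[0].squares == frozenset({(2, 2)})

    def test_chain_absorbed(self):
        counts = np.zeros((5, 8), dtype=int)
        counts[2, 1:7] = 6
        g = grid_from_counts(counts)
        aggs = grow_aggregates(g, "Tumor", {(2, 1)}, CAAConfig(growth_cutoff=5))
        assert aggs[0].squares == frozenset((2, c) for c in range(1, 7))

    def test_two_seeds_one_component_merge(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[1, :] = 7
        g = grid_from_counts(counts)
        aggs = grow_aggregates(g, "Tumor", {(1, 0), (1, 3)}, CAAConfig(growth_cutoff=5))
        assert len(aggs) == 1

    def test_seed_retained_below_cutoff(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 1
        g = grid_from_counts(counts)
        aggs = grow_aggregates(g, "Tumor", {(0, 0)}, CAAConfig(growth_cutoff=5))
        assert aggs[0].squares == frozenset({(0, 0)})

    def test_auto_cutoff_empty_grid(self):
        g = grid_from_counts(np.zeros((3, 3), dtype=int))
        assert grow_aggregates(g, "Tumor", set(), CAAConfig(growth_cutoff="auto")) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_connected_component_oracle(self, rng, connectivity):
        for _ in range(40):
            counts = rng.integers(0, 10, size=(10, 10))
            cfg = CAAConfig(growth_cutoff=int(rng.integers(1, 8)), connectivity=connectivity)
            g = grid_from_counts(counts)
            seeds = seed_squares(g, "Tumor", cfg)
            got = {a.squares for a in grow_aggregates(g, "Tumor", seeds, cfg)}
            assert got == oracle_components(counts, seeds, cfg.growth_cutoff, connectivity)

    def test_result_independent_of_seed_order(self, rng):
        counts = rng.integers(0, 9, size=(8, 8))
        g = grid_from_counts(counts)
        cfg = CAAConfig(growth_cutoff=4)
        seeds = list(seed_squares(g, "Tumor", cfg))
        a1 = {a.squares for a in grow_aggregates(g, "Tumor", seeds, cfg)}
        a2 = {a.squares for a in grow_aggregates(g, "Tumor", list(reversed(seeds)), cfg)}
        assert a1 == a2

    def test_lower_cutoff_never_shrinks(self, rng):
        counts = rng.integers(0, 10, size=(10, 10))
        g = grid_from_counts(counts)
        hi = {s for a in grow_aggregates(g, "Tumor", seed_squares(g, "Tumor", CAAConfig()), CAAConfig(growth_cutoff=6))
              for s in a.squares}
        lo = {s for a in grow_aggregates(g, "Tumor", seed_squares(g, "Tumor", CAAConfig()), CAAConfig(growth_cutoff=3))
              for s in a.squares}
        assert hi <= lo


class TestPolygons:
    def test_single_square_area(self):
        g = grid_from_counts(np.ones((3, 3), dtype=int), s=10.0)
        agg = Aggregate("Tumor", "F1", frozenset({(1, 1)}), g)
        aggregates_to_polygons([agg])
        assert agg.polygon.area == agg.area_um2 == 100.0

    def test_diagonal_contact_multipart_area_additive(self):
        g = grid_from_counts(np.ones((3, 3), dtype=int), s=10.0)
        agg = Aggregate("Tumor", "F1", frozenset({(0, 0), (1, 1)}), g)
        aggregates_to_polygons([agg])
        assert agg.polygon.area == pytest.approx(200.0)
        assert agg.area_um2 == 200.0

    def test_ring_has_interior_hole(self):
        squares = {(r, c) for r in range(3) for c in range(3)} - {(1, 1)}
        g = grid_from_counts(np.ones((3, 3), dtype=int), s=10.0)
        agg = Aggregate("Tumor", "F1", frozenset(squares), g)
        aggregates_to_polygons([agg])
        assert agg.polygon.area == pytest.approx(800.0)
        assert len(agg.polygon.interiors) == 1
        # rasterize back: square centers inside the polygon = member squares
        rec = {(r, c) for r in range(3) for c in range(3)
               if agg.polygon.covers(shapely.Point(10 * c + 5, 10 * r + 5))}
        assert rec == squares


class TestInfiltrationAreas:
    def agg(self, squares, label, g):
        return aggregates_to_polygons([Aggregate(label, g.fov_id, frozenset(squares), g)])[0]

    def test_identical_polygons_fraction_one(self):
        g = grid_from_counts(np.ones((4, 4), dtype=int))
        sq = {(0, 0), (0, 1), (1, 1)}
        ia = infiltration_areas([self.agg(sq, "Tumor", g)], [self.agg(sq, "CD3", g)])
        assert ia.infiltration_fraction == 1.0

    def test_disjoint_polygons_fraction_zero(self):
        g = grid_from_counts(np.ones((4, 4), dtype=int))
        ia = infiltration_areas([self.agg({(0, 0)}, "Tumor", g)], [self.agg({(3, 3)}, "CD3", g)])
        assert ia.area_um2 == 0.0 and ia.infiltration_fraction == 0.0
        assert ia.polygon.is_empty

    def test_half_overlap_grid_exact(self):
        g = grid_from_counts(np.ones((4, 4), dtype=int))
        tumor = {(0, 0), (0, 1), (1, 0), (1, 1)}
        cd3 = {(0, 0), (0, 1), (2, 2), (2, 3)}
        ia = infiltration_areas([self.agg(tumor, "Tumor", g)], [self.agg(cd3, "CD3", g)])
        assert ia.infiltration_fraction == 0.5
        assert ia.area_um2 <= min(ia.tumor_area_um2, ia.cd3_area_um2)

    def test_no_tumor_fraction_missing(self):
        g = grid_from_counts(np.ones((4, 4), dtype=int))
        ia = infiltration_areas([], [self.agg({(0, 0)}, "CD3", g)])
        assert ia.infiltration_fraction is None

    def test_mismatched_fovs_error(self):
        g1 = grid_from_counts(np.ones((2, 2), dtype=int), fov="F1")
        g2 = grid_from_counts(np.ones((2, 2), dtype=int), fov="F2")
        with pytest.raises(DataError, match="FOV"):
            infiltration_areas([self.agg({(0, 0)}, "Tumor", g1)], [self.agg({(0, 0)}, "CD3", g2)])


class TestCellsInRegion:
    def test_boundary_inclusive_partition(self):
        poly = shapely.box(0, 0, 10, 10)
        t = make_cells({"x": [5.0, 10.0, 11.0], "y": [5.0, 10.0, 5.0]})
        inside = region_mask(t, poly)
        assert inside.tolist() == [True, True, False]  # corner cell included
        assert len(cells_in_region(t, poly)) + int((~inside).sum()) == len(t)
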