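"""Occupancy classification, complexity and integrity scoring algebra."""

import numpy as np
import pandas as pd
import pytest
import shapely

import rewildmap as rw
from rewildmap.geodata_io import NODATA_FLOAT
from rewildmap.rewilding_scores import NODATA_CAT, NOT_PREDICTED, POTENTIAL, REALIZED


@pytest.fixture
def grid():
    return rw.GridSpec(0.0, 300.0, 30.0, 10, 10)


def _surface(grid, prob):
    return rw.SelectionSurface(grid, np.asarray(prob, float), species="sp")


def _range_left_half(grid):
    # polygon covering the left half of the grid (cell centres of cols 0-4)
    return shapely.box(0, 0, 150, 300)


class TestClassifyOccupancy:
    def test_category_definitions(self, grid):
        prob = np.full(grid.shape, 0.4)
        prob[:, :5] = 0.6
        occ = rw.classify_occupancy(_surface(grid, prob), _range_left_half(grid))
        assert (occ.categories[:, :5] == REALIZED).all()
        assert (occ.categories[:, 5:] == NOT_PREDICTED).all()
        prob2 = np.full(grid.shape, 0.6)
        occ2 = rw.classify_occupancy(_surface(grid, prob2), _range_left_half(grid))
        assert (occ2.categories[:, 5:] == POTENTIAL).all()

    def test_exact_threshold_not_predicted(self, grid):
        occ = rw.classify_occupancy(_surface(grid, np.full(grid.shape, 0.5)),
                                    _range_left_half(grid), threshold=0.5)
        assert (occ.categories == NOT_PREDICTED).all()

    def test_empty_range_all_potential(self, grid):
        occ = rw.classify_occupancy(_surface(grid, np.full(grid.shape, 0.9)), None)
        assert (occ.categories == POTENTIAL).all()
        assert not occ.mask(REALIZED).any()

    def test_partition_of_predicted(self, grid):
        rng = np.random.default_rng(0)
        prob = rng.uniform(0, 1, grid.shape)
        occ = rw.classify_occupancy(_surface(grid, prob), _range_left_half(grid))
        predicted = prob > 0.5
        assert np.array_equal(occ.mask(REALIZED) | occ.mask(POTENTIAL), predicted)
        assert not (occ.mask(REALIZED) & occ.mask(POTENTIAL)).any()

    def test_nodata_propagated(self, grid):
        prob = np.full(grid.shape, 0.9)
        prob[0, 0] = NODATA_FLOAT
        occ = rw.classify_occupancy(_surface(grid, prob), None)
        assert occ.categories[0, 0] == NODATA_CAT

    def test_bad_threshold_errors(self, grid):
        s = _surface(grid, np.full(grid.shape, 0.5))
        for t in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                rw.classify_occupancy(s, None, threshold=t)


def _occ(grid, codes):
    return rw.OccupancyMap(grid, np.asarray(codes), species="sp")


class TestFaunalComplexity:
    def test_per_cell_tally(self, grid):
        a = np.full(grid.shape, REALIZED)
        b = np.full(grid.shape, REALIZED)
        c = np.full(grid.shape, POTENTIAL)
        d = np.full(grid.shape, NOT_PREDICTED)
        cmx = rw.faunal_complexity([_occ(grid, m) for m in (a, b, c, d)])
        assert (cmx.realized == 2).all()
        assert (cmx.potential == 1).all()
        assert cmx.n_species == 4

    def test_all_species_realized(self, grid):
        maps = [_occ(grid, np.full(grid.shape, REALIZED)) for _ in range(4)]
        cmx = rw.faunal_complexity(maps)
        assert (cmx.realized == 4).all()

    def test_all_not_predicted(self, grid):
        maps = [_occ(grid, np.full(grid.shape, NOT_PREDICTED)) for _ in range(3)]
        cmx = rw.faunal_complexity(maps)
        assert not cmx.realized.any() and not cmx.potential.any()

    def test_grid_mismatch_errors(self, grid):
        other = rw.GridSpec(0.0, 150.0, 30.0, 5, 5)
        with pytest.raises(ValueError, match="grid"):
            rw.faunal_complexity([
                _occ(grid, np.full(grid.shape, REALIZED)),
                _occ(other, np.full(other.shape, REALIZED)),
            ])


class TestEcologicalIntegrity:
    def test_indicator_arithmetic(self, grid):
        codes = [POTENTIAL, NOT_PREDICTED, NOT_PREDICTED, NOT_PREDICTED]
        maps = [_occ(grid, np.full(grid.shape, c)) for c in codes]
        im = rw.ecological_integrity(maps, "after")
        assert np.unique(im.scores) == pytest.approx(0.75)  # (0+1+1+1)/4

    def test_before_scenario_empty_ranges(self, grid):
        # 2 of 4 species predicted at the cell -> (0+0+1+1)/4 = 0.5 before
        codes = [REALIZED, POTENTIAL, NOT_PREDICTED, NOT_PREDICTED]
        maps = [_occ(grid, np.full(grid.shape, c)) for c in codes]
        before = rw.ecological_integrity(maps, "before")
        assert np.unique(before.scores) == pytest.approx(0.5)
        after = rw.ecological_integrity(maps, "after")
        assert np.unique(after.scores) == pytest.approx(0.75)

    def test_full_realization_scores_one(self, grid):
        codes = [REALIZED, REALIZED, NOT_PREDICTED, NOT_PREDICTED]
        maps = [_occ(grid, np.full(grid.shape, c)) for c in codes]
        assert np.unique(rw.ecological_integrity(maps, "after").scores) == 1.0

    def test_lattice_values(self, grid):
        rng = np.random.default_rng(5)
        maps = [_occ(grid, rng.integers(0, 3, grid.shape)) for _ in range(4)]
        im = rw.ecological_integrity(maps, "after")
        assert set(np.unique(im.scores)) <= {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_mean_integrity_identity(self, grid):
        # mean integrity = 1 - mean(potential_count)/S
        rng = np.random.default_rng(6)
        maps = [_occ(grid, rng.integers(0, 3, grid.shape)) for _ in range(4)]
        im = rw.ecological_integrity(maps, "after")
        cmx = rw.faunal_complexity(maps)
        assert im.scores.mean() == pytest.approx(1 - cmx.potential.mean() / 4)

    def test_monotone_in_range_growth(self, grid):
        rng = np.random.default_rng(7)
        prob = rng.uniform(0, 1, grid.shape)
        small = rw.classify_occupancy(_surface(grid, prob), _range_left_half(grid))
        big = rw.classify_occupancy(_surface(grid, prob), shapely.box(0, 0, 300, 300))
        fixed = [_occ(grid, rng.integers(0, 3, grid.shape)) for _ in range(3)]
        im_small = rw.ecological_integrity([small] + fixed, "after")
        im_big = rw.ecological_integrity([big] + fixed, "after")
        assert (im_big.scores >= im_small.scores).all()
        assert (rw.faunal_complexity([big] + fixed).realized
                >= rw.faunal_complexity([small] + fixed).realized).all()


class TestAreaAccounting:
    def test_complexity_conservation(self, grid):
        rng = np.random.default_rng(8)
        maps = [_occ(grid, rng.integers(0, 3, grid.shape)) for _ in range(4)]
        cmx = rw.faunal_complexity(maps)
        boundary = rw.BoundaryPolygon(grid.envelope())
        table = rw.area_summary(cmx, boundary, field="realized", background=(0,))
        occupied = (cmx.realized >= 1).sum() * grid.cell_area_m2 / 1e6
        assert table.total_km2() == pytest.approx(occupied)

    def test_realized_fraction_printed_rows(self):
        assert rw.realized_fraction(4.37, 14.70) == 22.9
        assert rw.realized_fraction(40.06, 53.29) == 42.9
        assert rw.realized_fraction(1.11, 10.02) == 10.0
        assert rw.realized_fraction(3.0, 0.0) == 100.0

    def test_realized_fraction_zero_denominator(self):
        with pytest.raises(ValueError):
            rw.realized_fraction(0.0, 0.0)

    def test_high_integrity_from_bin_percents(self):
        def bins(p):
            t = pd.DataFrame({
                "label": [0.0, 0.25, 0.5, 0.75, 1.0, "total"],
                "area_km2": [0] * 6,
                "percent": p + [100.0],
            })
            return rw.AreaTable(t, denominator_km2=117.03)

        after = bins([0.4, 4.9, 20.9, 50.1, 23.7])
        before = bins([1.3, 7.7, 26.4, 45.5, 19.1])
        assert rw.high_integrity_percent(after) == pytest.approx(73.8)
        assert rw.high_integrity_percent(before) == pytest.approx(64.6)

    def test_integrity_delta_identical_maps(self, grid):
        rng = np.random.default_rng(9)
        maps = [_occ(grid, rng.integers(0, 2, grid.shape)) for _ in range(2)]
        im = rw.ecological_integrity(maps, "after")
        before = rw.IntegrityMap(grid, im.scores, im.n_species, "before")
        out = rw.integrity_delta(before, im, rw.BoundaryPolygon(grid.envelope()))
        pd.testing.assert_frame_equal(out["before"].table, out["after"].table)
        assert out["high_integrity_before_pct"] == out["high_integrity_after_pct"]
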