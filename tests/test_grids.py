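"""Raster I/O, occurrence thinning, layer pruning, extraction, partial ROC."""

import numpy as np
import pytest

import phyloniche as pn
from phyloniche.grids import GridFormatError, haversine_km, pearson_valid


@pytest.fixture
def landscape():
    return pn.make_landscape((30, 40), gradient=2.0, noise=0.3, seed=7)


class TestGridIO:
    def test_roundtrip(self, landscape, tmp_path):
        p = tmp_path / "x.asc"
        pn.write_grid(landscape, p)
        back = pn.read_grid(p)
        assert back.aligned_with(landscape)
        np.testing.assert_allclose(back.values, landscape.values, rtol=1e-9)

    def test_tiny_constant_grid(self, tmp_path):
        p = tmp_path / "c.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n5 5\n5 5\n")
        g = pn.read_grid(p)
        assert g.values.shape == (2, 2) and np.all(g.values == 5)

    def test_header_and_row_errors(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 2\ncellsize 1\n1 2\n3 4\n")
        with pytest.raises(GridFormatError, match="missing header"):
            pn.read_grid(p)
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n1 2 3\n4 5 6\n")
        with pytest.raises(GridFormatError, match="line"):
            pn.read_grid(p)

    def test_nodata_excluded_from_valid_values(self):
        g = pn.GridLayer(2, 2, 0, 0, 1.0, -9999, np.array([[1.0, -9999.0], [2.0, 3.0]]))
        assert sorted(g.valid_values()) == [1.0, 2.0, 3.0]


class TestThinning:
    def test_exact_duplicates_collapse(self):
        occ = pn.OccurrenceSet("sp", [10.0, 10.0], [20.0, 20.0])
        out = pn.thin_occurrences(occ, 0.5, seed=0)
        assert len(out) == 1

    def test_distant_points_survive(self):
        occ = pn.OccurrenceSet("sp", [10.0, 10.1], [20.0, 20.0])  # ~10 km apart
        assert len(pn.thin_occurrences(occ, 0.5, seed=0)) == 2

    def test_pairwise_distance_oracle(self):
        rng = np.random.default_rng(5)
        occ = pn.OccurrenceSet("sp", rng.uniform(-100.1, -100.0, 150),
                               rng.uniform(20.0, 20.1, 150))
        out = pn.thin_occurrences(occ, 2.0, seed=1)
        assert 0 < len(out) < len(occ)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert haversine_km(out.lon[i], out.lat[i],
                                    out.lon[j], out.lat[j]) >= 2.0

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        occ = pn.OccurrenceSet("sp", rng.uniform(-100.2, -100.0, 80),
                               rng.uniform(20.0, 20.2, 80))
        once = pn.thin_occurrences(occ, 3.0, seed=2)
        twice = pn.thin_occurrences(once, 3.0, seed=9)
        np.testing.assert_array_equal(once.lon, twice.lon)

    def test_one_point_per_cell(self, landscape):
        rng = np.random.default_rng(7)
        row = rng.integers(0, landscape.nrows, 200)
        col = rng.integers(0, landscape.ncols, 200)
        lon, lat = landscape.cell_center(row, col)
        out = pn.thin_occurrences(pn.OccurrenceSet("sp", lon, lat), 0.0,
                                  grid=landscape, seed=3)
        r2, c2 = landscape.cell_of(out.lon, out.lat)
        assert len(set(zip(r2, c2))) == len(out)

    def test_empty_input(self):
        out = pn.thin_occurrences(pn.OccurrenceSet("sp", [], []), 0.5)
        assert len(out) == 0


class TestLayerPruning:
    def test_duplicate_layer_dropped(self, landscape):
        kept = pn.prune_correlated_layers({"a": landscape, "b": landscape}, r_max=0.75)
        assert kept == ["a"]

    def test_independent_layers_kept(self):
        layers = {f"l{i}": pn.make_landscape((25, 25), noise=1.0, gradient=0.0, seed=i,
                                             smooth_sigma=1.0) for i in range(4)}
        assert pn.prune_correlated_layers(layers, r_max=0.75) == list(layers)

    def test_planted_collinearity_matches_bruteforce(self, landscape):
        layers = {"base": landscape}
        rng_seeds = iter(range(100, 120))
        for i in range(6):
            r = [0.95, 0.5, 0.9, 0.2, 0.8, 0.1][i]
            layers[f"s{i}"] = pn.make_correlated_landscape(landscape, r, seed=next(rng_seeds))
        kept = pn.prune_correlated_layers(layers, r_max=0.75)
        # brute-force greedy oracle over the full correlation matrix
        names = list(layers)
        flat = {n: layers[n].values.ravel() for n in names}
        R = {(a, b): np.corrcoef(flat[a], flat[b])[0, 1] for a in names for b in names}
        expect = []
        for n in names:
            if all(abs(R[(n, k)]) < 0.75 for k in expect):
                expect.append(n)
        assert kept == expect
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert abs(pearson_valid(layers[a], layers[b])) < 0.75

    def test_misaligned_layers_rejected(self, landscape):
        other = pn.make_landscape((30, 40), seed=1, west=0.0)
        with pytest.raises(ValueError, match="aligned"):
            pn.prune_correlated_layers({"a": landscape, "b": other})

    def test_pearson_matches_formula_oracle(self, landscape):
        other = pn.make_correlated_landscape(landscape, 0.6, seed=11)
        x, y = landscape.values.ravel(), other.values.ravel()
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert abs(pearson_valid(landscape, other) - manual) < 1e-12


class TestExtraction:
    def test_constant_layer(self):
        g = pn.GridLayer(3, 3, 0, 0, 1.0, -9999, np.full((3, 3), 4.2))
        occ = pn.OccurrenceSet("sp", [0.5, 2.5], [0.5, 2.5])
        np.testing.assert_allclose(pn.extract_values(g, occ), [4.2, 4.2])

    def test_nodata_yields_nan_and_outside_warns(self):
        vals = np.array([[1.0, -9999.0], [2.0, 3.0]])
        g = pn.GridLayer(2, 2, 0, 0, 1.0, -9999, vals)
        occ = pn.OccurrenceSet("sp", [1.5, 5.0], [1.5, 1.5])
        with pytest.warns(UserWarning, match="outside"):
            out = pn.extract_values(g, occ)
        assert len(out) == 1 and np.isnan(out[0])

    def test_index_arithmetic_oracle(self, landscape):
        rng = np.random.default_rng(8)
        lon = rng.uniform(landscape.west, landscape.east - 1e-9, 50)
        lat = rng.uniform(landscape.south, landscape.north - 1e-9, 50)
        got = pn.extract_values(landscape, pn.OccurrenceSet("sp", lon, lat))
        col = np.floor((lon - landscape.west) / landscape.cellsize).astype(int)
        rowup = np.floor((lat - landscape.south) / landscape.cellsize).astype(int)
        expect = landscape.values[landscape.nrows - 1 - rowup, col]
        np.testing.assert_allclose(got, expect)


class TestPartialROC:
    def test_constant_suitability_ratio_one(self):
        g = pn.GridLayer(10, 10, 0, 0, 0.1, -9999, np.full((10, 10), 0.5))
        occ = pn.OccurrenceSet("sp", np.linspace(0.05, 0.95, 8), np.full(8, 0.5))
        res = pn.partial_roc(g, occ, n_boot=50, seed=0)
        assert abs(res.mean_ratio - 1.0) < 1e-9

    def test_uniform_random_suitability_near_one(self):
        rng = np.random.default_rng(9)
        g = pn.GridLayer(60, 60, 0, 0, 0.05, -9999, rng.uniform(0, 1, (60, 60)))
        row = rng.integers(0, 60, 200)
        col = rng.integers(0, 60, 200)
        lon, lat = g.cell_center(row, col)
        res = pn.partial_roc(g, pn.OccurrenceSet("sp", lon, lat), n_boot=500, seed=1)
        assert abs(res.mean_ratio - 1.0) < 0.05

    def test_planted_signal_detected(self):
        clim = pn.make_landscape((50, 50), gradient=1.0, noise=0.1, seed=10)
        suit = pn.make_suitability(clim, mu=0.5, tau=0.15)
        occ = pn.sample_occurrences(suit, 60, seed=11)
        res = pn.partial_roc(suit, occ, n_boot=300, seed=12)
        assert res.mean_ratio > 1.0 and res.p_value < 0.05

    def test_too_few_points_rejected(self):
        g = pn.GridLayer(5, 5, 0, 0, 1.0, -9999, np.random.default_rng(0).uniform(0, 1, (5, 5)))
        with pytest.raises(ValueError, match="5 test points"):
            pn.partial_roc(g, pn.OccurrenceSet("sp", [1.0], [1.0]))
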