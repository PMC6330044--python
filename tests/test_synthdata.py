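"""Synthetic-data generator: ground-truth properties and determinism."""

import numpy as np
import pytest
from scipy import stats

import phyloniche as pn


class TestYuleTree:
    def test_two_tip_cherry(self):
        t = pn.simulate_yule_tree(2, 5.0, seed=0)
        assert t.n_tips == 2 and t.depth == pytest.approx(5.0)
        np.testing.assert_allclose(pn.vcv(t).C, 5.0 * np.eye(2))

    def test_bifurcating_internal_count(self):
        for seed in range(10):
            t = pn.simulate_yule_tree(15, 1.0, seed=seed)
            assert t.n_nodes == 2 * 15 - 1
            assert pn.is_ultrametric(t)
            assert t.depth == pytest.approx(1.0)

    def test_seed_determinism(self):
        a = pn.simulate_yule_tree(10, 2.0, seed=5)
        b = pn.simulate_yule_tree(10, 2.0, seed=5)
        assert pn.write_newick(a) == pn.write_newick(b)


class TestSimulateTrait:
    def test_zero_rate_constant(self, yule20):
        np.testing.assert_allclose(pn.simulate_trait(yule20, "bm", sigma2=0.0, z0=2.0), 2.0)

    def test_strong_ou_stationary_variance(self):
        tree = pn.simulate_yule_tree(2, 5.0, seed=1)
        X = pn.simulate_trait(tree, "ou", sigma2=1.0, alpha=4.0, seed=2, size=4000)
        # deep split: tips near OU stationary variance sigma2/(2 alpha)
        assert np.var(X[:, 0]) == pytest.approx(1.0 / 8.0, rel=0.15)

    def test_delta_one_equals_bm_distribution(self, yule20):
        a = pn.simulate_trait(yule20, "delta", delta=1.0, seed=3, size=800)[:, 0]
        b = pn.simulate_trait(yule20, "bm", seed=4, size=800)[:, 0]
        assert stats.ks_2samp(a, b).pvalue > 0.01


class TestLandscape:
    def test_zero_noise_planar(self):
        g = pn.make_landscape((20, 20), gradient=2.0, noise=0.0, seed=5)
        assert g.values.min() == pytest.approx(0.0)
        assert g.values.max() == pytest.approx(2.0)
        # a plane has zero second differences along any straight line
        d2 = np.diff(g.values, n=2, axis=0)
        np.testing.assert_allclose(d2, 0.0, atol=1e-9)

    def test_correlated_sibling_hits_target(self):
        base = pn.make_landscape((40, 40), seed=6)
        sib = pn.make_correlated_landscape(base, 0.9, seed=7)
        r = np.corrcoef(base.values.ravel(), sib.values.ravel())[0, 1]
        assert 0.85 <= r <= 0.95

    def test_seed_reproducibility(self):
        a = pn.make_landscape((15, 15), seed=8)
        b = pn.make_landscape((15, 15), seed=8)
        np.testing.assert_array_equal(a.values, b.values)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            pn.make_landscape((5, 5))


class TestSuitability:
    def test_optimum_cell_is_one(self):
        clim = pn.GridLayer(1, 3, 0, 0, 1.0, -9999, np.array([[1.0, 2.0, 3.0]]))
        s = pn.make_suitability(clim, mu=2.0, tau=0.5)
        assert s.values[0, 1] == pytest.approx(1.0)
        assert np.all((s.valid_values() > 0) & (s.valid_values() <= 1))

    def test_pno_recovers_optimum(self):
        clim = pn.make_landscape((40, 40), gradient=1.0, noise=0.1, seed=9)
        mu = 0.5
        suit = pn.make_suitability(clim, mu=mu, tau=0.1)
        prof = pn.compute_pno(clim, suit, n_bins=30)
        width = prof.centers[1] - prof.centers[0]
        assert abs(prof.centers[np.argmax(prof.mass)] - mu) <= width
        assert abs(pn.pno_weighted_mean(prof) - mu) <= width


class TestOccurrences:
    def test_point_mass_sampling(self):
        vals = np.zeros((4, 4))
        vals[2, 3] = 1.0
        suit = pn.GridLayer(4, 4, 0, 0, 1.0, -9999, vals)
        occ = pn.sample_occurrences(suit, 25, seed=10)
        r, c = suit.cell_of(occ.lon, occ.lat)
        assert np.all(r == 2) and np.all(c == 3)

    def test_frequencies_proportional_to_suitability(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.1, 1.0, (5, 5))
        suit = pn.GridLayer(5, 5, 0, 0, 1.0, -9999, vals)
        occ = pn.sample_occurrences(suit, 10000, seed=12)
        r, c = suit.cell_of(occ.lon, occ.lat)
        counts = np.zeros((5, 5))
        np.add.at(counts, (r, c), 1)
        expected = vals / vals.sum() * 10000
        assert stats.chisquare(counts.ravel(), expected.ravel()).pvalue > 0.01

    def test_all_zero_rejected(self):
        suit = pn.GridLayer(3, 3, 0, 0, 1.0, -9999, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pn.sample_occurrences(suit, 5)


class TestScenario:
    def test_full_determinism(self):
        sc = pn.SyntheticScenario(n_species=8, grid_shape=(25, 25),
                                  occurrences_per_species=30, seed=13)
        a = pn.generate_scenario(sc)
        b = pn.generate_scenario(pn.SyntheticScenario(
            n_species=8, grid_shape=(25, 25), occurrences_per_species=30, seed=13))
        assert pn.write_newick(a.tree) == pn.write_newick(b.tree)
        for v in a.climate:
            np.testing.assert_array_equal(a.climate[v].values, b.climate[v].values)
        for sp in a.occurrences:
            np.testing.assert_array_equal(a.occurrences[sp].lon, b.occurrences[sp].lon)

    def test_end_to_end_trait_recovery(self):
        # PNO-weighted means of per-variable suitability recover the planted
        # BM optima closely enough that BM remains competitive in model choice
        hits = 0
        ks = []
        for rep in range(15):
            sc = pn.SyntheticScenario(n_species=15, grid_shape=(50, 50),
                                      n_variables=1, occurrences_per_species=50,
                                      seed=500 + rep)
            data = pn.generate_scenario(sc)
            clim = data.climate["var1"]
            v = clim.valid_values()
            traits = {}
            for sp in data.tree.tip_labels:
                prof = pn.compute_pno(clim, data.suitability["var1"][sp], n_bins=50,
                                      vmin=v.min(), vmax=v.max())
                traits[sp] = pn.pno_weighted_mean(prof)
            tab = pn.rank_models(pn.fit_all_models(data.tree, traits))
            d = {f.model: dd for f, dd in zip(tab.fits, tab.delta_aic)}
            hits += d["bm"] < 2
            ks.append(pn.blomberg_k(data.tree, traits, n_perm=49, seed=rep)[0])
        assert hits >= 0.7 * 15
        assert 0.7 < np.mean(ks) < 1.3
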