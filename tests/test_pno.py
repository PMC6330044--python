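"""PNO profiles, weighted means, and ancestral tolerance reconstruction."""

import numpy as np
import pytest

import phyloniche as pn
from phyloniche.pno import ancestral_operator

from conftest import joint_bm_covariance


def _toy_layers():
    clim = pn.GridLayer(1, 3, 0, 0, 1.0, -9999, np.array([[1.0, 2.0, 3.0]]))
    suit = pn.GridLayer(1, 3, 0, 0, 1.0, -9999, np.array([[0.2, 0.3, 0.5]]))
    return clim, suit


class TestPNO:
    def test_three_cell_toy(self):
        clim, suit = _toy_layers()
        prof = pn.compute_pno(clim, suit, n_bins=3)
        np.testing.assert_allclose(prof.centers, [1, 2, 3])
        np.testing.assert_allclose(prof.mass, [0.2, 0.3, 0.5])
        assert pn.pno_weighted_mean(prof) == pytest.approx(2.3)

    def test_uniform_suitability_is_climate_histogram(self):
        clim = pn.make_landscape((20, 20), seed=1)
        ones = pn.GridLayer(20, 20, clim.west, clim.south, clim.cellsize,
                            clim.nodata, np.ones((20, 20)))
        prof = pn.compute_pno(clim, ones, n_bins=10)
        v = clim.valid_values()
        centers = np.linspace(v.min(), v.max(), 10)
        idx = np.round((v - v.min()) / (centers[1] - centers[0])).astype(int)
        hist = np.bincount(np.clip(idx, 0, 9), minlength=10) / len(v)
        np.testing.assert_allclose(prof.mass, hist, atol=1e-12)

    def test_point_mass_suitability(self):
        clim, _ = _toy_layers()
        suit = pn.GridLayer(1, 3, 0, 0, 1.0, -9999, np.array([[0.0, 0.0, 0.7]]))
        prof = pn.compute_pno(clim, suit, n_bins=3)
        np.testing.assert_allclose(prof.mass, [0, 0, 1])
        assert pn.pno_weighted_mean(prof) == pytest.approx(3.0)

    def test_scale_invariance_and_unit_mass(self):
        clim = pn.make_landscape((15, 15), seed=2)
        suit = pn.make_suitability(clim, mu=0.5, tau=0.2)
        half = pn.GridLayer(15, 15, clim.west, clim.south, clim.cellsize,
                            clim.nodata, suit.values * 0.5)
        p1 = pn.compute_pno(clim, suit, n_bins=20)
        p2 = pn.compute_pno(clim, half, n_bins=20)
        np.testing.assert_allclose(p1.mass, p2.mass, atol=1e-12)
        assert p1.mass.sum() == pytest.approx(1.0, abs=1e-9)
        m = pn.pno_weighted_mean(p1)
        assert p1.centers[0] <= m <= p1.centers[-1]

    def test_zero_suitability_rejected(self):
        clim, _ = _toy_layers()
        zero = pn.GridLayer(1, 3, 0, 0, 1.0, -9999, np.zeros((1, 3)))
        with pytest.raises(ValueError, match="zero"):
            pn.compute_pno(clim, zero, n_bins=3)


class TestAncestralStates:
    def test_constant_trait(self, balanced4):
        anc = pn.ancestral_states_bm(balanced4, dict.fromkeys("abcd", 2.5))
        assert all(abs(v - 2.5) < 1e-12 for v in anc.values())

    def test_cherry_root_midpoint(self, cherry):
        anc = pn.ancestral_states_bm(cherry, {"A": 0.0, "B": 2.0})
        assert anc[cherry.root] == pytest.approx(1.0)

    @pytest.mark.parametrize("n,seed", [(4, 1), (5, 2), (6, 3), (6, 4)])
    def test_conditional_mean_oracle(self, n, seed):
        tree = pn.simulate_yule_tree(n, 2.0, seed=seed)
        x = pn.simulate_bm_tips(tree, 1.0, seed=seed + 50)
        anc = pn.ancestral_states_bm(tree, x)

        tips, keys, V = joint_bm_covariance(tree.to_newick(digits=17))
        ti = [keys.index(t) for t in tree.tip_labels]
        Ctt = V[np.ix_(ti, ti)]
        Cinv = np.linalg.inv(Ctt)
        one = np.ones(n)
        z0 = (one @ Cinv @ x) / (one @ Cinv @ one)
        for node in tree.internal_nodes:
            key = frozenset(tree.tip_labels[t] for t in tree.clade_tips(node))
            if node == tree.root:
                expect = z0
            else:
                Snt = V[keys.index(key), ti]
                expect = z0 + Snt @ Cinv @ (x - z0 * one)
            assert abs(anc[node] - expect) < 1e-8

    def test_root_equals_gls_mean(self, yule20):
        x = pn.simulate_bm_tips(yule20, 1.0, seed=9)
        C = pn.vcv(yule20).C
        Cinv = np.linalg.inv(C)
        one = np.ones(20)
        z0 = (one @ Cinv @ x) / (one @ Cinv @ one)
        anc = pn.ancestral_states_bm(yule20, x)
        assert anc[yule20.root] == pytest.approx(z0, abs=1e-10)


class TestAncestralTolerance:
    def _point_profiles(self, tree, values):
        centers = np.array([0.0, 1.0, 2.0, 3.0])
        profs = {}
        for t, v in zip(tree.tip_labels, values):
            mass = np.zeros(4)
            mass[int(v)] = 1.0
            profs[t] = pn.PNOProfile("v", t, centers, mass)
        return profs

    def test_point_masses_deterministic(self, balanced4):
        profs = self._point_profiles(balanced4, [0, 0, 2, 2])
        tol = pn.ancestral_tolerance(balanced4, profs, n_iter=50, seed=0)
        det = pn.ancestral_states_bm(balanced4, dict(zip(balanced4.tip_labels, [0, 0, 2, 2])))
        np.testing.assert_allclose(tol.samples.std(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(tol.mean, [det[k] for k in tol.node_ids])

    def test_tip_summary_matches_weighted_mean(self, yule20):
        rng = np.random.default_rng(11)
        centers = np.linspace(0, 10, 30)
        profs = {}
        for t in yule20.tip_labels:
            w = rng.dirichlet(np.ones(30))
            profs[t] = pn.PNOProfile("v", t, centers, w)
        tol = pn.ancestral_tolerance(yule20, profs, n_iter=400, seed=12)
        for _, row in tol.tip_summary.iterrows():
            assert row["mean"] == pytest.approx(
                pn.pno_weighted_mean(profs[row["species"]]), abs=1e-9)
            assert row["lo80"] <= row["mean"] <= row["hi80"]

    def test_node_means_mc_stable(self, yule20):
        # peaked (PNO-like) tolerance profiles: node means converge quickly
        rng = np.random.default_rng(13)
        centers = np.linspace(0, 10, 25)
        profs = {}
        for t in yule20.tip_labels:
            mu = rng.uniform(2, 8)
            w = np.exp(-0.5 * ((centers - mu) / 0.6) ** 2)
            profs[t] = pn.PNOProfile("v", t, centers, w / w.sum())
        t_small = pn.ancestral_tolerance(yule20, profs, n_iter=100, seed=1)
        t_big = pn.ancestral_tolerance(yule20, profs, n_iter=1000, seed=2)
        assert np.max(np.abs(t_small.mean - t_big.mean)) < 0.02 * 10

    def test_missing_profile_rejected(self, cherry):
        with pytest.raises(ValueError, match="missing"):
            pn.ancestral_tolerance(cherry, {}, n_iter=10)


def test_ancestral_operator_rows_sum_to_one(yule20):
    # shifting all tips by c shifts every reconstruction by c
    A = ancestral_operator(yule20)
    np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-10)
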