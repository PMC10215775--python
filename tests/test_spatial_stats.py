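import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landcarbon.grid_core import build_fishnet
from landcarbon.spatial_stats import (
    bivariate_moran,
    build_weights,
    classify_z,
    getis_ord_gistar,
    global_morans_i,
    morans_i_bruteforce,
    pearson,
)


def lattice(nr, nc):
    """Fishnet-like table for a full nr×nc lattice."""
    ids = np.arange(nr * nc)
    return pd.DataFrame({"cell_id": ids, "row": ids // nc, "col": ids % nc})


class TestBuildWeights:
    def test_rook_neighbour_counts(self):
        W = build_weights(lattice(3, 3), "rook", row_standardize=False)
        deg = np.asarray(W.W.sum(axis=1)).ravel()
        assert deg[0] == 2  # corner
        assert deg[4] == 4  # centre

    def test_queen_centre_has_eight(self):
        W = build_weights(lattice(3, 3), "queen", row_standardize=False)
        assert np.asarray(W.W.sum(axis=1)).ravel()[4] == 8

    def test_row_standardised_rows_sum_to_one(self):
        W = build_weights(lattice(4, 5), "queen", row_standardize=True)
        np.testing.assert_allclose(np.asarray(W.W.sum(axis=1)).ravel(), 1.0, atol=1e-12)

    def test_island_warned(self):
        table = pd.DataFrame({"cell_id": [0, 1, 2], "row": [0, 0, 9], "col": [0, 1, 9]})
        with pytest.warns(UserWarning, match="island"):
            W = build_weights(table, "queen")
        assert list(W.islands()) == [2]

    def test_contiguity_symmetric_before_standardisation(self):
        W = build_weights(lattice(4, 4), "queen", row_standardize=False)
        assert (W.W != W.W.T).nnz == 0


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        nr = nc = 8
        vals = np.indices((nr, nc)).sum(axis=0) % 2
        W = build_weights(lattice(nr, nc), "rook", row_standardize=True)
        res = global_morans_i(vals.ravel().astype(float), W, n_perm=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_smooth_gradient_strongly_positive(self):
        vals = np.add.outer(np.arange(20), np.arange(20)).astype(float)
        W = build_weights(lattice(20, 20), "queen")
        res = global_morans_i(vals.ravel(), W, n_perm=0)
        assert res.I > 0.8

    def test_permutation_null_centres_on_expectation(self):
        rng = np.random.default_rng(0)
        W = build_weights(lattice(6, 6), "queen")
        n = 36
        vals = rng.random(n)
        Is = []
        for k in range(200):
            Is.append(global_morans_i(rng.permutation(vals), W, n_perm=0).I)
        assert np.mean(Is) == pytest.approx(-1 / (n - 1), abs=0.02)

    @pytest.mark.parametrize("size", [(3, 4), (5, 5), (7, 6), (12, 12)])
    def test_matches_bruteforce_double_sum(self, size):
        rng = np.random.default_rng(size[0] * 100 + size[1])
        vals = rng.random(size[0] * size[1])
        for scheme in ("rook", "queen"):
            W = build_weights(lattice(*size), scheme)
            fast = global_morans_i(vals, W, n_perm=0).I
            slow = morans_i_bruteforce(vals, W)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_p_value_seed_reproducible(self):
        rng = np.random.default_rng(1)
        vals = rng.random(36)
        W = build_weights(lattice(6, 6), "queen")
        a = global_morans_i(vals, W, n_perm=199, seed=5)
        b = global_morans_i(vals, W, n_perm=199, seed=5)
        assert a.p_sim == b.p_sim and a.p_greater == b.p_greater

    def test_constant_surface_rejected(self):
        W = build_weights(lattice(3, 3), "queen")
        with pytest.raises(ValueError, match="constant"):
            global_morans_i(np.ones(9), W)

    def test_null_p_values_uniform(self):
        """Under exchangeability the one-sided permutation p is uniform (KS)."""
        rng = np.random.default_rng(2)
        W = build_weights(lattice(6, 6), "queen")
        ps = [
            global_morans_i(rng.random(36), W, n_perm=199, seed=int(k)).p_greater
            for k in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGiStar:
    def make_weights(self, nr, nc):
        return build_weights(lattice(nr, nc), "queen", row_standardize=False, include_self=True)

    def test_single_spike_heats_its_neighbourhood(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.01, 100)
        vals[55] = 10.0
        res = getis_ord_gistar(vals, self.make_weights(10, 10))
        # every self-inclusive window containing the spike is equally hot,
        # so the maximum must fall in the spike's Moore neighbourhood
        hot = int(res.z_scores.argmax())
        assert abs(hot // 10 - 55 // 10) <= 1 and abs(hot % 10 - 55 % 10) <= 1
        assert res.z_scores[55] > 2.58
        assert res.classes[55] == "hot99"

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(4)
        vals = rng.random(64)
        W = self.make_weights(8, 8)
        z1 = getis_ord_gistar(vals, W).z_scores
        z2 = getis_ord_gistar(-vals, W).z_scores
        np.testing.assert_allclose(z1, -z2, atol=1e-10)

    def test_matches_per_cell_bruteforce(self):
        rng = np.random.default_rng(5)
        vals = rng.random(48)
        W = self.make_weights(6, 8)
        res = getis_ord_gistar(vals, W)
        Wd = W.W.toarray()
        n = vals.size
        xbar = vals.mean()
        S = np.sqrt((vals**2).sum() / n - xbar**2)
        for i in range(n):
            wi = Wd[i].sum()
            num = (Wd[i] * vals).sum() - xbar * wi
            den = S * np.sqrt((n * (Wd[i] ** 2).sum() - wi**2) / (n - 1))
            assert res.z_scores[i] == pytest.approx(num / den, abs=1e-10)

    def test_classification_affine_invariant(self):
        rng = np.random.default_rng(6)
        vals = rng.random(100)
        W = self.make_weights(10, 10)
        c1 = getis_ord_gistar(vals, W).classes
        c2 = getis_ord_gistar(3.5 * vals + 11.0, W).classes
        np.testing.assert_array_equal(c1, c2)

    def test_class_thresholds(self):
        z = np.array([-3.0, -2.0, -1.7, 0.0, 1.7, 2.0, 3.0])
        np.testing.assert_array_equal(
            classify_z(z), ["cold99", "cold95", "cold90", "ns", "hot90", "hot95", "hot99"]
        )

    def test_requires_self_inclusive_weights(self):
        W = build_weights(lattice(3, 3), "queen")
        with pytest.raises(ValueError, match="self"):
            getis_ord_gistar(np.arange(9.0), W)


class TestBivariateMoran:
    def setup_method(self):
        rng = np.random.default_rng(7)
        base = np.add.outer(np.arange(10), np.arange(10)).astype(float)
        self.x = (base + rng.normal(0, 1, (10, 10))).ravel()
        self.W = build_weights(lattice(10, 10), "queen")

    def test_self_pair_reduces_to_univariate(self):
        biv = bivariate_moran(self.x, self.x, self.W, n_perm=49, seed=0)
        uni = global_morans_i(self.x, self.W, n_perm=0)
        assert biv.global_i == pytest.approx(uni.I, abs=1e-10)

    def test_negated_pair_flips_sign(self):
        biv = bivariate_moran(self.x, -self.x, self.W, n_perm=49, seed=0)
        uni = global_morans_i(self.x, self.W, n_perm=0)
        assert biv.global_i == pytest.approx(-uni.I, abs=1e-10)

    def test_opposite_gradients_label_hl_lh(self):
        """Anti-aligned smooth fields cluster as high-low / low-high."""
        y = -self.x
        res = bivariate_moran(self.x, y, self.W, n_perm=199, seed=1)
        sig = res.labels[res.labels != "ns"]
        assert len(sig) > 0
        assert np.isin(sig, ["HL", "LH"]).mean() > 0.9

    def test_local_values_sum_to_global(self):
        res = bivariate_moran(self.x, np.roll(self.x, 3), self.W, n_perm=9, seed=2)
        assert res.local_i.mean() == pytest.approx(res.global_i, abs=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(5), np.arange(5.0))
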