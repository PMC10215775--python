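import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from landcarbon.rs_indices import endisi, mndwi
from landcarbon.synthetic_data import (
    SynthSpec,
    directional_flows,
    make_validation_benchmark,
    synth_drivers,
    synth_expansion,
    synth_landscape,
    synth_reflectance,
    synth_transition,
)
from landcarbon.transitions import crosstab, transition_probabilities
from conftest import grid_from_codes


class TestSynthLandscape:
    def test_zero_length_is_spatially_random(self):
        """Same-class join frequency matches the independence expectation."""
        spec = SynthSpec(seed=1, shape=(128, 128), autocorr_length=0.0)
        g = synth_landscape(spec)
        p = (g.counts() / g.counts().sum()).values
        same = (g.codes[:, :-1] == g.codes[:, 1:]).mean()
        same_v = (g.codes[:-1, :] == g.codes[1:, :]).mean()
        expected = float((p**2).sum())
        assert abs(same - expected) < 0.015
        assert abs(same_v - expected) < 0.015

    def test_long_length_grows_patches(self):
        spec = SynthSpec(seed=2, shape=(256, 256), autocorr_length=8.0)
        g = synth_landscape(spec)
        sizes = []
        for code in g.class_table:
            lab, n = ndimage.label(g.codes == code)
            if n:
                sizes.append((g.codes == code).sum() / n)
        assert np.mean(sizes) > 10

    def test_proportions_approached(self):
        props = {"cultivated": 0.5, "forest": 0.3, "grassland": 0.1, "water": 0.05,
                 "construction": 0.04, "unused": 0.01}
        spec = SynthSpec(seed=3, shape=(128, 128), proportions=props, autocorr_length=3.0)
        g = synth_landscape(spec)
        shares = g.counts() / g.counts().sum()
        for cls, target in props.items():
            assert shares[cls] == pytest.approx(target, abs=0.05)

    def test_seed_determinism(self):
        spec = SynthSpec(seed=4, shape=(64, 64))
        np.testing.assert_array_equal(synth_landscape(spec).codes, synth_landscape(spec).codes)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="16"):
            SynthSpec(seed=0, shape=(8, 8))


class TestSynthTransition:
    def test_identity_matrix_changes_nothing(self):
        g = synth_landscape(SynthSpec(seed=5, shape=(64, 64)))
        P = pd.DataFrame(np.eye(6), index=list(g.class_table.values()), columns=list(g.class_table.values()))
        g2, ledger = synth_transition(g, P, 0.0, seed=6)
        np.testing.assert_array_equal(g.codes, g2.codes)
        assert np.trace(ledger.values) == g.codes.size

    def test_empirical_rate_matches_binomial(self):
        g = grid_from_codes(np.full((512, 512), 2))
        classes = ["cultivated", "forest", "grassland", "water", "construction", "unused"]
        P = pd.DataFrame(np.eye(6), index=classes, columns=classes)
        P.loc["forest", "forest"] = 0.9
        P.loc["forest", "construction"] = 0.1
        _, ledger = synth_transition(g, P, 0.0, seed=7)
        rate = ledger.loc["forest", "construction"] / ledger.loc["forest"].sum()
        assert rate == pytest.approx(0.1, abs=0.01)

    def test_ledger_equals_crosstab(self):
        g = synth_landscape(SynthSpec(seed=8, shape=(96, 96), autocorr_length=4.0))
        classes = list(g.class_table.values())
        rng = np.random.default_rng(9)
        M = rng.random((6, 6)) + 5 * np.eye(6)
        P = pd.DataFrame(M / M.sum(axis=1, keepdims=True), index=classes, columns=classes)
        g2, ledger = synth_transition(g, P, 3.0, seed=10)
        tm = crosstab(g, g2)
        counts = np.round(tm.areas.values / g.cell_area_km2).astype(int)
        np.testing.assert_array_equal(counts, ledger.values)

    def test_adjacency_preference_concentrates_change_at_edges(self):
        g = synth_landscape(SynthSpec(seed=11, shape=(128, 128), autocorr_length=6.0))
        classes = list(g.class_table.values())
        M = np.eye(6) * 0.9 + 0.02
        P = pd.DataFrame(M / M.sum(axis=1, keepdims=True), index=classes, columns=classes)
        kernel = np.ones((3, 3)); kernel[1, 1] = 0
        frac_same = ndimage.convolve((g.codes[:, :] != 0).astype(float), kernel, mode="constant")
        changed_weak = synth_transition(g, P, 0.0, seed=12)[0].codes != g.codes
        changed_strong = synth_transition(g, P, 30.0, seed=12)[0].codes != g.codes
        # under strong preference, changed cells sit next to their new class more often
        def adjacency_score(g2codes, changed):
            hits = []
            for code in range(1, 7):
                cnt = ndimage.convolve((g.codes == code).astype(float), kernel, mode="constant")
                sel = changed & (g2codes == code)
                if sel.any():
                    hits.append(cnt[sel].mean())
            return np.mean(hits)

        weak = adjacency_score(synth_transition(g, P, 0.0, seed=12)[0].codes, changed_weak)
        strong = adjacency_score(synth_transition(g, P, 30.0, seed=12)[0].codes, changed_strong)
        assert strong > weak


class TestSynthExpansion:
    def test_flows_realised_exactly(self):
        g = synth_landscape(SynthSpec(seed=13, shape=(96, 96), autocorr_length=4.0))
        classes = list(g.class_table.values())
        flows = pd.DataFrame(0, index=classes, columns=classes)
        flows.loc["forest", "construction"] = 120
        flows.loc["cultivated", "construction"] = 60
        g2, ledger = synth_expansion(g, flows, seed=14)
        assert ledger.loc["forest", "construction"] == 120
        assert ledger.loc["cultivated", "construction"] == 60
        tm_counts = np.round(crosstab(g, g2).areas.values / g.cell_area_km2).astype(int)
        np.testing.assert_array_equal(tm_counts, ledger.values)

    def test_directional_flows_keep_dominant_direction(self):
        from landcarbon import datasets

        A = directional_flows(datasets.transfer_matrix_2000_2020().areas)
        assert A.loc["cultivated", "construction"] > 0  # 387.23 dominates 32.26
        assert A.loc["construction", "cultivated"] == 0.0
        # folding preserves row totals
        np.testing.assert_allclose(
            A.sum(axis=1), datasets.transfer_matrix_2000_2020().row_totals(), atol=1e-9
        )


class TestSynthDrivers:
    def test_zero_coefficients_uninformative(self):
        g = synth_landscape(SynthSpec(seed=15, shape=(128, 128), autocorr_length=4.0))
        coeffs = {"flat1": {c: 0.0 for c in g.class_table.values()}}
        drivers = synth_drivers(g, coeffs, seed=16)
        y = (g.codes == 2).ravel()
        auc = roc_auc_score(y, drivers.layers["flat1"].ravel())
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_strong_coefficient_separates_class(self):
        g = synth_landscape(SynthSpec(seed=17, shape=(128, 128), autocorr_length=4.0))
        coeffs = {"strong": {c: (5.0 if c == "forest" else 0.0) for c in g.class_table.values()}}
        drivers = synth_drivers(g, coeffs, seed=18, noise_sigma=0.2)
        y = (g.codes == 2).ravel()
        assert roc_auc_score(y, drivers.layers["strong"].ravel()) > 0.95

    def test_seed_determinism(self):
        g = synth_landscape(SynthSpec(seed=19, shape=(64, 64)))
        a = synth_drivers(g, seed=20)
        b = synth_drivers(g, seed=20)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])


class TestSynthReflectance:
    def test_noise_free_urban_has_positive_endisi(self):
        g = grid_from_codes(np.full((4, 4), 5))
        stack = synth_reflectance(g, sigma=0.0, seed=0)
        assert (endisi(stack) > 0).all()

    def test_noise_free_water_has_positive_mndwi(self):
        g = grid_from_codes(np.full((4, 4), 4))
        stack = synth_reflectance(g, sigma=0.0, seed=0)
        assert (mndwi(stack) > 0).all()

    def test_seed_determinism(self):
        g = grid_from_codes(np.full((16, 16), 2))
        a = synth_reflectance(g, sigma=0.05, seed=21)
        b = synth_reflectance(g, sigma=0.05, seed=21)
        np.testing.assert_array_equal(a.nir, b.nir)

    def test_negative_sigma_rejected(self):
        g = grid_from_codes(np.full((4, 4), 1))
        with pytest.raises(ValueError, match="sigma"):
            synth_reflectance(g, sigma=-0.1)


class TestRecoveryChain:
    def test_transition_probabilities_recover_p_star(self, benchmark):
        """Estimate P̂ from the generated pair; strength-0 replicate at 256²."""
        from landcarbon.synthetic_data import benchmark_spec

        spec = benchmark_spec(23, (256, 256))
        g1 = synth_landscape(spec)
        g2, _ = synth_transition(g1, spec.P_star, 0.0, seed=24)
        P_hat = transition_probabilities(crosstab(g1, g2)).P
        err = np.abs(P_hat.values - spec.P_star.loc[P_hat.index, P_hat.columns].values).max()
        assert err < 0.05  # 256² replicate; the 512² run tightens this to 0.02
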