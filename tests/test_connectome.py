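"""Connectome IO, weight assembly, synthetic generation, shuffling."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cortexwm import (ConnectomeBundle, load_connectome, save_connectome,
                      rescale_fln, assemble_projection_weights,
                      generate_synthetic_connectome,
                      shuffle_projection_weights, fit_hierarchy_from_sln,
                      build_gradient_spec, compute_balance_constants,
                      build_network, integrate, CANONICAL_AREAS)
from cortexwm.connectome import canonical_area_name


class TestBundleIO:
    def test_round_trip(self, tmp_path):
        b = generate_synthetic_connectome(n_areas=8, seed=11)
        save_connectome(b, tmp_path / "c")
        b2 = load_connectome(tmp_path / "c")
        assert b2.areas == b.areas
        np.testing.assert_allclose(b2.FLN, b.FLN, rtol=1e-12)
        np.testing.assert_allclose(b2.SLN, b.SLN, rtol=1e-12)

    def test_diagonal_violation_named(self):
        b = generate_synthetic_connectome(n_areas=6, seed=0)
        b.FLN[3, 3] = 0.1
        with pytest.raises(ValueError, match="diagonal"):
            b.validate()

    def test_sln_range_violation_named(self):
        b = generate_synthetic_connectome(n_areas=6, seed=0)
        i, j = np.argwhere(b.FLN > 0)[0]
        b.SLN[i, j] = 1.2
        with pytest.raises(ValueError, match=r"SLN out of \[0, 1\]"):
            b.validate()

    def test_canonical_name_matching(self):
        assert canonical_area_name("9/46 v") == "9/46v"
        assert canonical_area_name("7a") == "7A"
        with pytest.raises(KeyError):
            canonical_area_name("V99")


class TestRescale:
    def test_row_normalization(self):
        F = np.array([[0.0, 1.0, 3.0], [0.5, 0.0, 0.5], [2.0, 0.0, 0.0]])
        W = rescale_fln(F, k1=1.0, k2=1.0, normalize=True)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("f, expected", [
        (1.0, 1.2),                       # k1 * 1**k2
        (0.0, 0.0),                       # absent projections stay absent
        (1e-5, 1.2 * 10 ** -1.5),          # power-law compression
    ])
    def test_power_law(self, f, expected):
        W = rescale_fln(np.array([[0.0, f], [f, 0.0]]), normalize=False)
        assert W[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_bad_exponent_rejected(self):
        with pytest.raises(ValueError):
            rescale_fln(np.eye(2) * 0, k2=0.0)


class TestWeightAssembly:
    def _assemble(self, bundle, **kw):
        h = fit_hierarchy_from_sln(bundle.SLN, bundle.FLN, bundle.areas)
        grad = build_gradient_spec(h.h, bundle.areas)
        W = rescale_fln(bundle.FLN)
        return assemble_projection_weights(bundle, W, grad,
                                           compute_balance_constants(), **kw)

    def test_pure_feedforward_is_excitatory_only(self):
        b = generate_synthetic_connectome(seed=2)
        b.SLN[b.FLN > 0] = 1.0
        w = self._assemble(b)
        assert np.allclose(w.W_EI, 0.0)
        assert w.W_EE.sum() > 0

    def test_cib_scale_zero_disables_inhibitory_routing(self):
        b = generate_synthetic_connectome(seed=2)
        w = self._assemble(b, cib_scale=0.0)
        assert np.allclose(w.W_EI, 0.0)

    def test_fef_cap_limits_inhibitory_fraction(self):
        b = generate_synthetic_connectome(seed=2)
        w = self._assemble(b, cib_scale=5.0, fef_cap=0.4)
        # W_EI = Wg * min(cib*(1-SLN), cap) and W_EE = Wg * SLN, so the
        # per-projection inhibitory fraction is W_EI * SLN / W_EE
        for t in ("8l", "8m"):
            i = b.index(t)
            mask = (b.FLN[i] > 0) & (b.SLN[i] > 1e-6)
            frac = (w.W_EI[i, mask] * b.SLN[i, mask]
                    / np.maximum(w.W_EE[i, mask], 1e-30))
            assert np.all(frac <= 0.4 + 1e-9)
        # a non-FEF target with mostly-feedback input exceeds the FEF cap
        other = b.index("V1")
        mask = (b.FLN[other] > 0) & (b.SLN[other] > 1e-6)
        frac = (w.W_EI[other, mask] * b.SLN[other, mask]
                / np.maximum(w.W_EE[other, mask], 1e-30))
        assert frac.max() > 0.4

    def test_inhibitory_fraction_saturates_at_one(self):
        b = generate_synthetic_connectome(seed=2)
        w = self._assemble(b, cib_scale=1e9)
        # once cib_scale * (1 - SLN) exceeds the cap, the inhibitory
        # fraction pins at 1 (0.4 for FEF targets): W_EI * SLN == W_EE
        fef = [b.index("8l"), b.index("8m")]
        for i in range(b.n_areas):
            mask = (b.FLN[i] > 0) & (b.SLN[i] > 1e-6) & (b.SLN[i] < 1 - 1e-9)
            frac = (w.W_EI[i, mask] * b.SLN[i, mask]
                    / np.maximum(w.W_EE[i, mask], 1e-30))
            cap = 0.4 if i in fef else 1.0
            np.testing.assert_allclose(frac, cap, rtol=1e-9)


class TestSyntheticGenerator:
    def test_determinism(self):
        a = generate_synthetic_connectome(seed=9)
        b = generate_synthetic_connectome(seed=9)
        np.testing.assert_array_equal(a.FLN, b.FLN)
        np.testing.assert_array_equal(a.SLN, b.SLN)
        np.testing.assert_array_equal(a.excitability, b.excitability)

    def test_heavy_tail_spans_four_decades(self):
        b = generate_synthetic_connectome(seed=9)
        pos = b.FLN[b.FLN > 0]
        assert pos.max() / pos.min() >= 1e4

    def test_passes_validation_and_uses_canonical_names(self):
        b = generate_synthetic_connectome(seed=9)
        assert b.validate() is b
        assert b.areas == CANONICAL_AREAS

    def test_hierarchy_recovery(self):
        b = generate_synthetic_connectome(seed=9)
        fit = fit_hierarchy_from_sln(b.SLN, b.FLN, b.areas)
        H = np.array(b.meta["latent_hierarchy"])
        assert spearmanr(H, fit.h).statistic >= 0.95

    def test_feedforward_convention(self):
        b = generate_synthetic_connectome(seed=9)
        H = np.array(b.meta["latent_hierarchy"])
        up = (H[:, None] > H[None, :]) & (b.FLN > 0)   # low -> high
        assert np.all(b.SLN[up] > 0.5)


class TestShuffle:
    def test_preserves_multiset_and_zeros(self):
        b = generate_synthetic_connectome(seed=4)
        W = rescale_fln(b.FLN)
        Ws = shuffle_projection_weights(W, seed=0)
        assert np.array_equal(np.sort(W[W > 0]), np.sort(Ws[Ws > 0]))
        assert np.array_equal(W == 0, Ws == 0) or np.array_equal(
            np.sort(np.argwhere(W > 0), axis=0),
            np.sort(np.argwhere(Ws > 0), axis=0))

    def test_seed_determinism_and_degenerate_case(self):
        W = np.zeros((4, 4)); W[0, 1] = 0.7
        np.testing.assert_array_equal(shuffle_projection_weights(W, 1), W)
        b = generate_synthetic_connectome(seed=4)
        Wf = rescale_fln(b.FLN)
        np.testing.assert_array_equal(shuffle_projection_weights(Wf, 5),
                                      shuffle_projection_weights(Wf, 5))


class TestHomogeneity:
    def test_doubling_G_doubles_long_range_current(self):
        """Two-area probe: long-range input scales linearly with G."""
        from conftest import make_toy_bundle
        b = make_toy_bundle(2)
        n1 = build_network(b, mode="custom", G=0.1, J_max=0.3, J_min=0.25)
        n2 = build_network(b, mode="custom", G=0.2, J_max=0.3, J_min=0.25)
        S_A = np.array([0.2, 0.3])
        i1 = n1.G * (n1.weights.W_EE @ S_A)
        i2 = n2.G * (n2.weights.W_EE @ S_A)
        np.testing.assert_allclose(i2, 2 * i1, rtol=1e-12)
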