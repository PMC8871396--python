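"""Attractor census: enumeration, statistics, and survival to silencing."""

import numpy as np
import pytest

from cortexwm import (enumerate_attractors, participation_index,
                      size_rate_correlation, silencing_survival,
                      integrate, build_network)
from cortexwm.census import AttractorPattern, CensusResult, brute_force_census
from cortexwm.network import _BatchState


def _pattern(active, rates=None, size_rate=None):
    active = np.asarray(active, bool)
    n = active.size
    rates = np.asarray(rates if rates is not None
                       else np.where(active, 20.0, 0.0), float)
    return AttractorPattern(active=active,
                            pool=np.where(active, 0, -1),
                            mean_rates=rates, S=np.zeros((n, 3)))


def _census(patterns, areas=None):
    n = patterns[0].active.size
    return CensusResult(patterns=patterns,
                        areas=areas or [f"A{i:02d}" for i in range(n)],
                        n_samples=10, n_converged=10, n_discarded=0,
                        relax_time=1.0, threshold=5.0, seed=0,
                        G=0.1, J_max=0.5)


class TestStatistics:
    def test_participation_counting(self):
        pats = [_pattern([1, 1, 0]), _pattern([1, 0, 0]),
                _pattern([1, 1, 1]), _pattern([1, 0, 1])]
        pi = participation_index(_census(pats))
        np.testing.assert_allclose(pi, [1.0, 0.5, 0.5])

    def test_participation_empty_census_warns(self):
        c = _census([_pattern([1, 0])])
        c.patterns = []
        with pytest.warns(UserWarning):
            pi = participation_index(c)
        assert np.all(pi == 0)

    def test_size_rate_correlation_constructed(self):
        # rates strictly increasing with size -> correlation 1
        pats = [_pattern([1, 0, 0, 0], rates=[10, 0, 0, 0]),
                _pattern([1, 1, 0, 0], rates=[20, 20, 0, 0]),
                _pattern([1, 1, 1, 0], rates=[30, 30, 30, 0])]
        assert size_rate_correlation(_census(pats)) == pytest.approx(1.0)

    def test_degenerate_variance_signalled(self):
        pats = [_pattern([1, 0, 0], rates=[20, 0, 0]),
                _pattern([1, 1, 0], rates=[20, 20, 0]),
                _pattern([1, 1, 1], rates=[20, 20, 20])]
        with pytest.raises(ValueError, match="degenerate"):
            size_rate_correlation(_census(pats))

    def test_too_few_patterns_rejected(self):
        with pytest.raises(ValueError):
            size_rate_correlation(_census([_pattern([1, 0])]))


class TestEnumeration:
    def test_determinism(self, toy2_net):
        a = enumerate_attractors(toy2_net, n_samples=32, relax_time=3.0,
                                 seed=5, dt=1e-3)
        b = enumerate_attractors(toy2_net, n_samples=32, relax_time=3.0,
                                 seed=5, dt=1e-3)
        assert [p.key for p in a.patterns] == [p.key for p in b.patterns]

    def test_sampling_monotonicity(self, toy2_net):
        """More samples can only add patterns (same seed stream prefix)."""
        small = enumerate_attractors(toy2_net, n_samples=16, relax_time=3.0,
                                     seed=5, dt=1e-3)
        big = enumerate_attractors(toy2_net, n_samples=48, relax_time=3.0,
                                   seed=5, dt=1e-3)
        assert {p.key for p in small.patterns} <= {p.key for p in big.patterns}

    def test_decoupled_subcritical_network_has_no_attractors(self):
        from conftest import make_toy_bundle
        b = make_toy_bundle(3)
        net = build_network(b, mode="custom", G=0.0, J_max=0.42, J_min=0.21)
        c = enumerate_attractors(net, n_samples=32, relax_time=3.0, seed=0,
                                 dt=1e-3)
        assert c.n_attractors == 0


class TestOracleEquivalence:
    """The sampling census against exhaustive relaxation on toy networks."""

    def _oracle_patterns(self, net, threshold, relax_time=3.0):
        """Independent path: relax every binary seed with the numpy
        integrator (not the census kernel) and binarize by hand."""
        N = net.n_areas
        sp = net.spontaneous
        found = {}
        for mask in range(2 ** N):
            st = _BatchState.spontaneous(net)
            for i in range(N):
                if (mask >> i) & 1:
                    st.S[0, i, 0] = 0.3
            res = integrate(net, duration=relax_time, dt=1e-3, noise=False,
                            init=st)
            rA, rB = res.rates[-1, :, 0], res.rates[-1, :, 1]
            dom = np.maximum(rA, rB)
            active = dom > threshold
            if active.any():
                found["".join("1" if a else "0" for a in active)] = True
        return set(found)

    def test_two_area_census_matches_brute_force(self, toy2_net):
        thr = toy2_net.spontaneous["r_A"] + 5.0
        cen = enumerate_attractors(toy2_net, n_samples=64, relax_time=3.0,
                                   seed=1, dt=1e-3)
        bf = brute_force_census(toy2_net, relax_time=3.0, dt=1e-3)
        oracle = self._oracle_patterns(toy2_net, thr)
        assert {p.key for p in cen.patterns} == oracle
        assert {p.key for p in bf.patterns} == oracle

    def test_three_area_census_matches_brute_force(self, toy3_net):
        thr = toy3_net.spontaneous["r_A"] + 5.0
        cen = enumerate_attractors(toy3_net, n_samples=128, relax_time=3.0,
                                   seed=1, dt=1e-3)
        oracle = self._oracle_patterns(toy3_net, thr)
        assert {p.key for p in cen.patterns} == oracle


class TestSilencingSurvival:
    def test_empty_set_preserves_everything(self, toy2_net):
        cen = enumerate_attractors(toy2_net, n_samples=32, relax_time=3.0,
                                   seed=1, dt=1e-3)
        assert cen.n_attractors > 0
        surv = silencing_survival(toy2_net, cen, [[]])
        assert surv == [100.0]

    def test_three_area_survival_matches_oracle(self, toy3_net):
        """Survival percentages equal exhaustive re-relaxation."""
        cen = enumerate_attractors(toy3_net, n_samples=128, relax_time=3.0,
                                   seed=1, dt=1e-3)
        sets = [["A02"], ["A00"], ["A01", "A02"]]
        surv = silencing_survival(toy3_net, cen, sets, relax_time=3.0,
                                  dt=1e-3)
        for areas, pct in zip(sets, surv):
            mask = np.zeros(3, bool)
            for a in areas:
                mask[toy3_net.index(a)] = True
            alive = 0
            for p in cen.patterns:
                st = _BatchState.spontaneous(toy3_net)
                st.S[0] = p.S
                st.S[0, mask, :] = 0.0
                st.r[0] = 0.0
                from cortexwm import SilencingSpec
                res = integrate(toy3_net, duration=3.0, dt=1e-3, noise=False,
                                init=st,
                                silencing=SilencingSpec(areas=areas,
                                                        window=None))
                dom = np.maximum(res.rates[-1, :, 0], res.rates[-1, :, 1])
                if np.any(dom > cen.threshold):
                    alive += 1
            assert pct == pytest.approx(100.0 * alive / cen.n_attractors)
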