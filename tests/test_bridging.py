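"""Bridging functions: closed forms, reductions, inverses, MC oracle."""

import zlib

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from fsgc.bridging import (BridgeSpec, PairBridge, bridge_dtau_dr,
                           bridge_inverse, bridge_tau, bvn_cdf,
                           mc_bridge_oracle)

CC = BridgeSpec("continuous")
BB = BridgeSpec("binary", (0.5,), (0.3,))
OO = BridgeSpec("ordinal", (-0.6, 0.1, 0.6), (-0.6, 0.1, 0.6))
TT = BridgeSpec("truncated", (0.5,), (0.5,))
ALL = [CC, BB, OO, TT]


class TestBvnCdf:
    def test_against_scipy_reference(self, rng):
        for _ in range(50):
            h, k = rng.normal(size=2) * 2
            r = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal(cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-13)

    def test_edges(self):
        assert bvn_cdf(np.inf, 0.3, 0.5) == pytest.approx(norm.cdf(0.3))
        assert bvn_cdf(-np.inf, 0.3, 0.5) == 0.0
        assert bvn_cdf(0.0, 0.0, 0.6) == pytest.approx(
            0.25 + np.arcsin(0.6) / (2 * np.pi), abs=1e-13)
        assert bvn_cdf(0.4, 0.9, 1.0) == pytest.approx(norm.cdf(0.4))
        assert bvn_cdf(0.4, -0.2, -1.0) == pytest.approx(
            max(norm.cdf(0.4) + norm.cdf(-0.2) - 1, 0.0), abs=1e-14)


class TestBridgeForms:
    def test_continuous_is_arcsine(self):
        r = np.linspace(-0.999, 0.999, 41)
        np.testing.assert_allclose(bridge_tau(r, CC),
                                   2 / np.pi * np.arcsin(r), atol=1e-12)

    def test_binary_balanced_limit_is_half(self):
        sp = BridgeSpec("binary", (0.0,), (0.0,))
        assert bridge_tau(1.0, sp) == pytest.approx(0.5, abs=1e-4)

    def test_ordinal_two_levels_reduces_to_binary(self):
        sp2 = BridgeSpec("ordinal", (0.4,), (-0.2,))
        spB = BridgeSpec("binary", (0.4,), (-0.2,))
        for r in np.linspace(-0.95, 0.95, 21):
            assert bridge_tau(r, sp2) == pytest.approx(bridge_tau(r, spB),
                                                       abs=1e-10)

    def test_truncated_no_truncation_limit_is_continuous(self):
        sp = BridgeSpec("truncated", (-8.0,), (-8.0,))
        diff = max(abs(bridge_tau(r, sp) - bridge_tau(r, CC))
                   for r in np.linspace(-0.9, 0.9, 13))
        assert diff < 1e-4

    @pytest.mark.parametrize("spec", ALL, ids=["CC", "BB", "OO", "TT"])
    def test_zero_at_independence(self, spec):
        assert bridge_tau(0.0, spec) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("spec", ALL, ids=["CC", "BB", "OO", "TT"])
    def test_strictly_increasing(self, spec):
        r = np.linspace(-0.95, 0.95, 41)
        f = bridge_tau(r, spec)
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize("spec", [
        CC,
        BridgeSpec("binary", (0.0,), (0.0,)),
        BridgeSpec("ordinal", (-0.8, 0.0, 0.8), (-0.8, 0.0, 0.8)),
    ], ids=["CC", "BB-antisym", "OO-antisym"])
    def test_odd_symmetry_for_antisymmetric_cutoffs(self, spec):
        # flipping the latent sign reverses the category order exactly when
        # each point's cutoff vector is antisymmetric about 0; truncation
        # breaks the symmetry (the zero atom is one-sided), so no TT case
        for r in (0.2, 0.55, 0.85):
            assert bridge_tau(-r, spec) == pytest.approx(
                -bridge_tau(r, spec), abs=1e-10)

    @pytest.mark.parametrize("spec", ALL, ids=["CC", "BB", "OO", "TT"])
    def test_derivative_matches_finite_difference(self, spec):
        h = 1e-5
        for r in (-0.6, 0.1, 0.7):
            fd = (bridge_tau(r + h, spec) - bridge_tau(r - h, spec)) / (2 * h)
            assert bridge_dtau_dr(r, spec) == pytest.approx(fd, rel=2e-3)


class TestInverse:
    def test_continuous_closed_form(self):
        assert bridge_inverse(1 / 3, CC) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("spec", [
        BridgeSpec("binary", (0.4,), (-0.4,)),
        BridgeSpec("ordinal", (-0.5, 0.5), (-0.5, 0.5)),
        BridgeSpec("truncated", (0.0,), (0.0,)),
    ], ids=["BB", "OO", "TT"])
    def test_zero_tau_maps_to_zero(self, spec):
        assert bridge_inverse(0.0, spec) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("spec", ALL, ids=["CC", "BB", "OO", "TT"])
    def test_round_trip(self, spec):
        for r in np.arange(-0.9, 0.91, 0.3):
            tau = bridge_tau(r, spec)
            assert bridge_inverse(tau, spec) == pytest.approx(r, abs=1e-6)

    def test_out_of_range_tau_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            r = bridge_inverse(0.99, BB)
        assert r == pytest.approx(1.0, abs=1e-6)


class TestMonteCarloOracle:
    def test_arcsine_value(self):
        mc = mc_bridge_oracle(0.5, CC, n_mc=10 ** 6, seed=1)
        assert abs(mc.tau - 1 / 3) < 0.004

    def test_balanced_binary_independence(self):
        sp = BridgeSpec("binary", (0.0,), (0.0,))
        mc = mc_bridge_oracle(0.0, sp, n_mc=10 ** 6, seed=2)
        assert abs(mc.tau) < 3 * mc.se

    @pytest.mark.parametrize("r", [-0.75, 0.3, 0.9])
    @pytest.mark.parametrize("spec", ALL, ids=["CC", "BB", "OO", "TT"])
    def test_certification_within_four_se(self, spec, r):
        mc = mc_bridge_oracle(r, spec, n_mc=10 ** 6,
                              seed=zlib.crc32(repr((spec.kind, r)).encode()) % 2 ** 31)
        assert abs(bridge_tau(r, spec) - mc.tau) < 4 * mc.se

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            mc_bridge_oracle(0.3, CC, n_mc=100)


class TestPairBridge:
    def test_consistency_with_scalar_api(self, rng):
        cj = rng.uniform(-0.5, 0.8, size=6)
        cjp = rng.uniform(-0.5, 0.8, size=6)
        r = rng.uniform(-0.9, 0.9, size=6)
        for kind in ("binary", "truncated"):
            pb = PairBridge(kind, cj[:, None], cjp[:, None])
            got = pb.tau(r)
            tol = 2e-4 if kind == "truncated" else 1e-12
            for i in range(6):
                sp = BridgeSpec(kind, (cj[i],), (cjp[i],))
                assert got[i] == pytest.approx(bridge_tau(r[i], sp), abs=tol)

    def test_vector_inverse_round_trip(self, rng):
        cj = np.sort(rng.uniform(-0.8, 0.8, size=(5, 3)), axis=1)
        pb = PairBridge("ordinal", cj, cj[::-1])
        r = rng.uniform(-0.9, 0.9, size=5)
        np.testing.assert_allclose(pb.inverse(pb.tau(r)), r, atol=1e-8)
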