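"""Error-cost ingredients: alpha, beta, the t density, the residual."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from flexpst import (
    GroupSummary,
    InferenceWeights,
    TestGeometry,
    alpha_of_x,
    beta_of_x,
    epsilon_of_x,
    geometry_equal_variance,
    geometry_from_summaries,
    stationarity_residual,
    t_density,
)


class TestGeometryBuilders:
    def test_measured_geometry_replica1(self, replica1, weights):
        g = geometry_from_summaries(*replica1, weights)
        assert g.delta == pytest.approx(1.4910, abs=5e-4)
        assert g.nu == pytest.approx(69.2528, abs=5e-3)
        assert g.k == pytest.approx(0.125)

    def test_k_is_data_free(self, replica1, replica2, weights):
        g1 = geometry_from_summaries(*replica1, weights)
        g2 = geometry_from_summaries(*replica2, weights)
        assert g1.k == g2.k == weights.C * weights.pr / (2 * (1 - weights.pr))

    def test_equal_variance_arithmetic(self, weights):
        g = geometry_equal_variance(50, weights)
        assert g.nu == 98.0
        assert g.delta == pytest.approx(2.5)
        g2 = geometry_equal_variance(2, InferenceWeights(pr=0.5, C=0.25, d=1.0))
        assert (g2.nu, g2.delta) == (2.0, pytest.approx(1.0))

    def test_equal_variance_matches_measured_when_sds_equal(self, weights):
        n, sd = 37, 1.7
        a = GroupSummary(n, 0.0, sd)
        b = GroupSummary(n, 1.0, sd)
        measured = geometry_from_summaries(a, b, weights)
        apriori = geometry_equal_variance(n, weights)
        assert measured.nu == pytest.approx(apriori.nu, rel=1e-12)
        assert measured.delta == pytest.approx(apriori.delta, rel=1e-12)

    def test_rejects_tiny_arm(self, weights):
        with pytest.raises(ValueError):
            geometry_equal_variance(1, weights)

    def test_delta_shrinks_to_zero_with_d(self, replica1):
        small = InferenceWeights(pr=0.5, C=0.25, d=1e-12)
        g = geometry_from_summaries(*replica1, small)
        assert g.delta == pytest.approx(0.0, abs=1e-11)


class TestTailFunctions:
    def test_alpha_at_zero_and_symmetry(self):
        assert alpha_of_x(0.0, 10.0) == pytest.approx(1.0)
        assert alpha_of_x(-1.7, 10.0) == pytest.approx(alpha_of_x(1.7, 10.0))

    def test_alpha_gaussian_limit(self):
        assert alpha_of_x(1.96, 1e6) == pytest.approx(0.05, abs=1e-3)

    def test_beta_degenerate_points(self):
        assert beta_of_x(0.0, 12.0, 1.5) == pytest.approx(0.0)
        assert beta_of_x(40.0, 12.0, 1.5) == pytest.approx(1.0, abs=1e-9)

    def test_alpha_beta_complement_when_delta_zero(self):
        xs = np.linspace(-6, 6, 41)
        for nu in (1.5, 5.0, 30.0, 250.0):
            np.testing.assert_allclose(
                alpha_of_x(xs, nu) + beta_of_x(xs, nu, 0.0), 1.0, atol=1e-12)

    def test_alpha_decreasing_beta_increasing(self):
        xs = np.linspace(0.05, 8, 100)
        a = alpha_of_x(xs, 20.0)
        b = beta_of_x(xs, 20.0, 2.0)
        assert np.all(np.diff(a) < 0)
        assert np.all(np.diff(b) > 0)


class TestTDensity:
    def test_cauchy_value_at_zero(self):
        assert t_density(0.0, 1.0) == pytest.approx(1.0 / np.pi, abs=1e-14)

    def test_even_and_matches_reference_density(self):
        xs = np.linspace(-8, 8, 81)
        for nu in (0.7, 3.0, 69.25, 400.0):
            np.testing.assert_allclose(t_density(xs, nu), t_density(-xs, nu),
                                       atol=1e-15)
            np.testing.assert_allclose(t_density(xs, nu),
                                       stats.t.pdf(xs, df=nu), atol=1e-12)

    def test_integrates_to_one(self):
        for nu in (2.5, 30.0):
            total, _ = integrate.quad(lambda x: t_density(x, nu), -np.inf, np.inf)
            assert total == pytest.approx(1.0, abs=1e-6)


class TestEpsilon:
    def test_limits(self, weights):
        g = TestGeometry(nu=40.0, delta=2.0, k=weights.k)
        assert epsilon_of_x(0.0, g, weights).epsilon == pytest.approx(
            1.0 - weights.pr, abs=1e-9)
        assert epsilon_of_x(500.0, g, weights).epsilon == pytest.approx(
            weights.C * weights.pr, abs=1e-9)

    def test_affine_in_alpha_when_delta_zero(self, weights):
        g = TestGeometry(nu=25.0, delta=0.0, k=weights.k)
        for x in (0.3, 1.1, 2.7):
            r = epsilon_of_x(x, g, weights)
            assert r.epsilon == pytest.approx(0.125 + 0.375 * r.alpha, abs=1e-12)

    def test_weighted_sum_identity(self, weights):
        g = TestGeometry(nu=12.0, delta=1.3, k=weights.k)
        r = epsilon_of_x(1.9, g, weights)
        assert r.epsilon == pytest.approx(
            weights.C * weights.pr * r.beta + (1 - weights.pr) * r.alpha, abs=1e-15)


def _power_form_residual(x, nu, delta, k):
    """Oracle: the ratio of (1 + x^2/nu) powers, normalizers cancelled."""
    p = -(nu + 1.0) / 2.0
    num = (1.0 + x * x / nu) ** p
    den = (1.0 + (x - delta) ** 2 / nu) ** p + (1.0 + (x + delta) ** 2 / nu) ** p
    return num / den - k


class TestStationarityResidual:
    def test_even_in_x(self, weights):
        g = TestGeometry(nu=30.0, delta=1.8, k=weights.k)
        for x in (0.4, 1.3, 3.2):
            assert stationarity_residual(-x, g) == pytest.approx(
                stationarity_residual(x, g), abs=1e-14)

    def test_matches_power_form(self):
        for nu in (4.0, 30.0, 120.0):
            for delta in (0.6, 1.5, 3.0):
                for x in np.linspace(0.05, 9.0, 25):
                    g = TestGeometry(nu=nu, delta=delta, k=0.125)
                    assert stationarity_residual(x, g) == pytest.approx(
                        _power_form_residual(x, nu, delta, 0.125), abs=1e-10)

    def test_constant_when_delta_zero(self):
        g = TestGeometry(nu=20.0, delta=0.0, k=0.2)
        for x in (0.1, 1.0, 5.0):
            assert stationarity_residual(x, g) == pytest.approx(0.5 - 0.2, abs=1e-12)

    def test_replica1_sign_change_near_bisection_root(self, replica1, weights):
        g = geometry_from_summaries(*replica1, weights)
        # independent bisection oracle on the sign change
        lo, hi = 1.0, 3.0
        assert stationarity_residual(lo, g) > 0 > stationarity_residual(hi, g)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if stationarity_residual(mid, g) > 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(2.1694, abs=2e-3)

    @given(nu=st.floats(3, 500), delta=st.floats(0.3, 6), x=st.floats(0.01, 10))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_log_space_form_agrees_with_power_form(self, nu, delta, x):
        g = TestGeometry(nu=nu, delta=delta, k=0.125)
        assert stationarity_residual(x, g) == pytest.approx(
            _power_form_residual(x, nu, delta, 0.125), abs=1e-9)
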