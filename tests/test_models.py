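import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import j0

from saxsflow.models import (
    DisplacedCoreShellParams,
    GaussianChainParams,
    MicelleParams,
    RandomFlightParams,
    concentric_core_shell_intensity,
    displaced_core_shell_intensity,
    effective_radius,
    eps_core_from_outer,
    eps_outer_from_core,
    gaussian_chain_intensity,
    random_flight_sf,
    sphere_amplitude,
)


class TestSphereAmplitude:
    def test_normalization_and_bounds(self):
        x = np.geomspace(1e-8, 50, 2000)
        phi = sphere_amplitude(x)
        assert sphere_amplitude(0.0) == 1.0
        assert np.all(np.abs(phi) <= 1.0)

    def test_closed_form_at_pi(self):
        # sin(pi) = 0, cos(pi) = -1 -> Phi(pi) = 3/pi^2
        assert sphere_amplitude(np.pi) == pytest.approx(3 / np.pi**2, rel=1e-12)

    def test_first_zero_at_tan_x_equals_x(self):
        # independent bracketed root search of the analytic amplitude
        root = brentq(
            lambda x: 3 * (np.sin(x) - x * np.cos(x)) / x**3, 4.0, 5.0, xtol=1e-12
        )
        assert root == pytest.approx(4.4934094579, abs=1e-6)
        assert sphere_amplitude(root) == pytest.approx(0.0, abs=1e-12)

    def test_series_matches_analytic_at_crossover(self):
        # the Taylor branch agrees with the analytic form at the switch point
        for x in (0.009, 0.0095, 0.0099):
            analytic = 3 * (np.sin(x) - x * np.cos(x)) / x**3
            assert sphere_amplitude(x) == pytest.approx(analytic, rel=1e-9)


class TestGeometry:
    def test_effective_radius_limits(self):
        assert effective_radius(10.0, 1.0, 0.7) == pytest.approx(10.0)
        assert effective_radius(10.0, 2.0, 0.0) == pytest.approx(20.0)
        assert effective_radius(10.0, 2.0, np.pi / 2) == pytest.approx(10.0)
        assert effective_radius(10.0, 2.0, np.pi / 4) == pytest.approx(
            10.0 * np.sqrt(2.5)
        )

    def test_micelle_short_axes(self):
        # polar semi-axes of the two surfactant micelle cores
        assert effective_radius(22.7, 0.60, 0.0) == pytest.approx(13.62, abs=0.005)
        assert effective_radius(21.0, 0.64, 0.0) == pytest.approx(13.44, abs=0.005)

    @given(
        R2=st.floats(2.0, 50.0),
        eps2=st.floats(0.3, 5.0),
        Dshell=st.floats(0.0, 30.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_shell_uniformity_round_trip(self, R2, eps2, Dshell):
        """The forward relation applied to (R1, eps1) recovers eps2."""
        eps1 = eps_outer_from_core(R2, eps2, Dshell)
        if Dshell == 0:
            assert eps1 == pytest.approx(eps2)
        else:
            assert eps_core_from_outer(R2 + Dshell, eps1, Dshell) == pytest.approx(
                eps2, rel=1e-12
            )

    def test_uniform_shell_thickness_at_pole_and_equator(self):
        R2, eps2, D = 13.7, 1.8, 10.1
        eps1 = eps_outer_from_core(R2, eps2, D)
        R1 = R2 + D
        # equator
        assert effective_radius(R1, eps1, np.pi / 2) - effective_radius(
            R2, eps2, np.pi / 2
        ) == pytest.approx(D)
        # pole
        assert effective_radius(R1, eps1, 0.0) - effective_radius(
            R2, eps2, 0.0
        ) == pytest.approx(D)

    def test_table_geometry_example(self):
        assert eps_outer_from_core(13.7, 1.8, 10.1) == pytest.approx(
            (1.8 * 13.7 + 10.1) / 23.8, rel=1e-12
        )


class TestDisplacedCoreShell:
    def test_forward_limit(self, complex_params_10p5):
        p = complex_params_10p5
        I = displaced_core_shell_intensity(p, np.array([1e-8]))
        assert I[0] == pytest.approx((p.k1 + p.k2) ** 2, rel=1e-10)

    def test_reduces_to_concentric_at_zero_offset(self, q_grid):
        p = DisplacedCoreShellParams(
            R2=13.7, eps2=1.8, Dshell=10.1, s=0.0, k1=1.6e-9, k2=-0.7e-9
        )
        m = MicelleParams(Rcore=13.7, eps=1.8, Dhead=10.1, k1=1.6e-9, k2=-0.7e-9)
        Id = displaced_core_shell_intensity(p, q_grid)
        Ic = concentric_core_shell_intensity(m, q_grid)
        np.testing.assert_allclose(Id, Ic, rtol=1e-12)

    def test_geometry_violation_rejected(self):
        with pytest.raises(ValueError, match="s <= R1 - R2"):
            DisplacedCoreShellParams(
                R2=13.7, eps2=1.8, Dshell=10.1, s=10.2, k1=1e-9, k2=-1e-9
            )

    def test_nonnegative(self, complex_params_10p5, q_grid):
        assert np.all(displaced_core_shell_intensity(complex_params_10p5, q_grid) >= 0)

    @pytest.mark.parametrize("variant", ["amplitude", "exact"])
    def test_brute_force_orientation_average(self, complex_params_10p5, variant):
        """Quadrature matches a fine midpoint-rule average over cos(theta)
        (and azimuth, for the exact variant) to better than 0.1%."""
        p = complex_params_10p5
        q = np.linspace(0.05, 0.3, 6)
        n = 200_000 if variant == "amplitude" else 800
        u = (np.arange(n) + 0.5) / n  # cos(theta) on (0, 1)
        theta = np.arccos(u)
        r1 = effective_radius(p.R1, p.eps1, theta)
        r2 = effective_radius(p.R2, p.eps2, theta)
        ref = []
        for qi in q:
            A1 = p.k1 * sphere_amplitude(qi * r1)
            A2 = p.k2 * sphere_amplitude(qi * r2)
            if variant == "amplitude":
                ref.append(np.mean((A1 + A2 * j0(qi * p.s * np.sin(theta))) ** 2))
            else:
                phi = (np.arange(800) + 0.5) / 800 * 2 * np.pi
                phase = np.cos(
                    qi * p.s * np.sin(theta)[:, None] * np.cos(phi)[None, :]
                )
                ref.append(
                    np.mean(A1**2 + A2**2 + 2 * A1 * A2 * np.mean(phase, axis=1))
                )
        I = displaced_core_shell_intensity(p, q, variant=variant)
        np.testing.assert_allclose(I, ref, rtol=1e-3)

    def test_quadrature_convergence(self, q_grid):
        """Doubling the quadrature order changes nothing beyond 1e-6
        relative, for all end-state geometries."""
        geoms = [
            (15.0, 7.6, 3.4, 7.4),
            (13.2, 8.8, 3.4, 3.2),
            (10.2, 11.5, 2.1, 2.1),
            (10.1, 13.7, 1.8, 1.9),
        ]
        for Dhead, Rcore, eps, s in geoms:
            p = DisplacedCoreShellParams(
                R2=Rcore, eps2=eps, Dshell=Dhead, s=s, k1=1.6e-9, k2=-0.7e-9
            )
            I1 = displaced_core_shell_intensity(p, q_grid, order=76)
            I2 = displaced_core_shell_intensity(p, q_grid, order=152)
            np.testing.assert_allclose(I1, I2, rtol=1e-6)

    def test_concentric_sphere_matches_closed_form(self):
        """eps = 1: the core-shell sphere has an analytic amplitude."""
        k1, k2, R1, R2 = 2.0e-9, -0.8e-9, 25.0, 15.0
        m = MicelleParams(Rcore=R2, eps=1.0, Dhead=R1 - R2, k1=k1, k2=k2)
        q = np.geomspace(0.005, 0.4, 50)
        exact = (k1 * sphere_amplitude(q * R1) + k2 * sphere_amplitude(q * R2)) ** 2
        np.testing.assert_allclose(
            concentric_core_shell_intensity(m, q), exact, rtol=1e-9
        )


class TestRandomFlight:
    def test_single_complex_is_unity(self):
        S = random_flight_sf(RandomFlightParams(Nmic=1.0, Dmic=50.0), np.geomspace(0.01, 0.5, 50))
        np.testing.assert_allclose(S, 1.0)

    @given(Nmic=st.floats(1.0, 12.0))
    @settings(max_examples=40, deadline=None)
    def test_forward_limit_is_cluster_size(self, Nmic):
        S0 = random_flight_sf(RandomFlightParams(Nmic=Nmic, Dmic=50.0), np.array([1e-9]))
        assert S0[0] == pytest.approx(Nmic, rel=1e-6)

    def test_node_of_phase_factor(self):
        # q*Dmic = pi -> x = 0 -> S = 1 for N = 2
        q = np.array([np.pi / 50.0])
        S = random_flight_sf(RandomFlightParams(Nmic=2.0, Dmic=50.0), q)
        assert S[0] == pytest.approx(1.0, abs=1e-12)

    def test_non_integer_weighting(self):
        q = np.geomspace(0.005, 0.5, 80)
        S24 = random_flight_sf(RandomFlightParams(Nmic=2.4, Dmic=50.0), q)
        S2 = random_flight_sf(RandomFlightParams(Nmic=2.0, Dmic=50.0), q)
        S3 = random_flight_sf(RandomFlightParams(Nmic=3.0, Dmic=50.0), q)
        np.testing.assert_allclose(S24, 0.6 * S2 + 0.4 * S3, rtol=1e-12)

    def test_continuity_at_integers(self):
        q = np.geomspace(0.005, 0.5, 40)
        below = random_flight_sf(RandomFlightParams(Nmic=3.0 - 1e-9, Dmic=50.0), q)
        at = random_flight_sf(RandomFlightParams(Nmic=3.0, Dmic=50.0), q)
        np.testing.assert_allclose(below, at, atol=1e-7)


class TestGaussianChain:
    def test_forward_value_and_monotonicity(self):
        p = GaussianChainParams(Rg=30.0, I0=0.0244)
        q = np.geomspace(1e-6, 0.5, 300)
        I = gaussian_chain_intensity(p, q)
        assert I[0] == pytest.approx(0.0244, rel=1e-6)
        assert np.all(np.diff(I) < 0)

    def test_closed_form_at_x_one(self):
        # x = 1: D(1) = 2(e^-1 - 1 + 1)/1 = 2/e
        p = GaussianChainParams(Rg=30.0, I0=1.0)
        I = gaussian_chain_intensity(p, np.array([1.0 / 30.0]))
        assert I[0] == pytest.approx(2.0 / np.e, rel=1e-9)

    def test_high_q_asymptote(self):
        p = GaussianChainParams(Rg=30.0, I0=1.0)
        q = np.array([1.0])  # x = 900
        I = gaussian_chain_intensity(p, q)
        x = (q[0] * p.Rg) ** 2
        assert I[0] == pytest.approx(2.0 / x, rel=5e-3)
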