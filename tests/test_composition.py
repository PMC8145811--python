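import numpy as np
import pytest

from saxsflow.composition import (
    PER_MM_PER_CM3,
    ContrastSet,
    SolutionComposition,
    aggregation_number,
    chi_sds,
    complex_contrasts,
    gaussian_chain_prefactor,
    implied_protein_concentration,
    max_npro,
    micelle_intensity_absolute,
    number_density,
)


class TestAggregationNumber:
    def test_one_chain_fills_a_sphere(self, contrasts):
        R = (3 * contrasts.v_chain / (4 * np.pi)) ** (1 / 3)
        assert aggregation_number(R, 1.0, contrasts.v_chain) == pytest.approx(1.0)

    def test_surfactant_micelles(self, contrasts):
        # printed values 85 (SDS) and 70 (C12E8); the C12 chain volume
        # convention reproduces them within ~2%
        assert aggregation_number(22.7, 0.60, contrasts.v_chain) == pytest.approx(
            85, rel=0.02
        )
        assert aggregation_number(21.0, 0.64, contrasts.v_chain) == pytest.approx(
            70, rel=0.02
        )


class TestChiSds:
    @pytest.mark.parametrize(
        "sds,c12e8,expected",
        [(8.5, 10.4, 0.45), (8.5, 19.8, 0.30), (5.0, 0.0, 1.0)],
    )
    def test_mole_fractions(self, sds, c12e8, expected):
        assert chi_sds(sds, c12e8) == pytest.approx(expected, abs=0.005)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_sds(0.0, 0.0)


class TestContrasts:
    def test_protein_free_water_shell_has_zero_contrast(self, contrasts):
        """A shell of pure water is contrast-matched: k1 = 0."""
        # zero head groups: use a contrast set whose head has water density
        import dataclasses

        v_head = 60.0
        b_head = v_head * 1e-24 * contrasts.rho_solvent  # exactly water-like
        cs = dataclasses.replace(contrasts, v_head_sds=v_head, b_head_sds=b_head)
        k1, k2, water = complex_contrasts(13.0, 1.0, 10.0, 0.0, cs)
        assert k1 == pytest.approx(0.0, abs=1e-25)
        assert 0 <= water < 1

    def test_k1_monotone_in_npro(self, contrasts):
        k1a, _, _ = complex_contrasts(13.7, 1.8, 15.0, 1.0, contrasts)
        k1b, _, _ = complex_contrasts(13.7, 1.8, 15.0, 2.0, contrasts)
        assert k1b > k1a

    def test_overfilled_shell_rejected(self, contrasts):
        with pytest.raises(ValueError, match="inconsistent"):
            complex_contrasts(13.7, 1.8, 5.0, 4.0, contrasts)

    def test_mass_balance_exact(self, contrasts):
        """shell volume = heads + protein + water, exactly."""
        Rcore, eps, D, Npro = 13.7, 1.8, 10.1, 0.98
        _, _, water_frac = complex_contrasts(Rcore, eps, D, Npro, contrasts)
        from saxsflow.models import eps_outer_from_core

        v2 = 4 * np.pi / 3 * eps * Rcore**3
        eps1 = eps_outer_from_core(Rcore, eps, D)
        v1 = 4 * np.pi / 3 * eps1 * (Rcore + D) ** 3
        v_shell = v1 - v2
        n_agg = v2 / contrasts.v_chain
        v_water = water_frac * v_shell
        assert n_agg * contrasts.v_head_sds + Npro * contrasts.v_protein + v_water == (
            pytest.approx(v_shell, rel=1e-12)
        )

    def test_hand_bookkeeping_oracle(self, contrasts):
        """k1 for the saturated end-state geometry, recomputed longhand."""
        from saxsflow.models import eps_outer_from_core

        Rcore, eps, D, Npro = 13.7, 1.8, 10.1, 0.98
        k1, k2, _ = complex_contrasts(Rcore, eps, D, Npro, contrasts)
        v2 = 4 * np.pi / 3 * eps * Rcore**3
        n_agg = v2 / contrasts.v_chain
        eps1 = eps_outer_from_core(Rcore, eps, D)
        v1 = 4 * np.pi / 3 * eps1 * (Rcore + D) ** 3
        db_head = contrasts.b_head_sds - contrasts.v_head_sds * 1e-24 * contrasts.rho_solvent
        db_pro = contrasts.b_protein - contrasts.v_protein * 1e-24 * contrasts.rho_solvent
        k1_hand = (n_agg * db_head + Npro * db_pro) * v1 / (v1 - v2)
        assert k1 == pytest.approx(k1_hand, rel=1e-12)
        assert (k1 + k2) > 0  # I(0) positive

    def test_max_npro_consistent_with_contrasts(self, contrasts):
        cap = max_npro(13.7, 1.8, 10.1, contrasts)
        complex_contrasts(13.7, 1.8, 10.1, 0.99 * cap, contrasts)  # fits
        with pytest.raises(ValueError):
            complex_contrasts(13.7, 1.8, 10.1, 1.01 * cap, contrasts)


class TestNumberDensity:
    def test_unit_conversion(self):
        comp = SolutionComposition(C_SDS_total=1.0, C_SDS_free=0.0, Nmic=1.0)
        assert number_density(comp, 100.0) == pytest.approx(6.022e15, rel=1e-3)

    def test_zero_bound_sds(self):
        comp = SolutionComposition(C_SDS_total=2.0, C_SDS_free=2.0)
        assert number_density(comp, 85.0) == 0.0

    def test_implied_protein_concentration_diagnostic(self, contrasts):
        """The saturated-complex composition implies roughly the pipetted
        protein concentration (2 mg/mL before mixing, 1 after)."""
        comp = SolutionComposition(
            c_protein=2.0, C_SDS_total=10.5, C_SDS_free=3.7, Npro=0.98, Nmic=1.0
        )
        n_agg = aggregation_number(13.7, 1.8, contrasts.v_chain)
        implied = implied_protein_concentration(comp, n_agg, contrasts.protein_mass)
        assert implied == pytest.approx(comp.c_protein, rel=0.25)

    def test_absolute_scale_round_trip(self, contrasts):
        """Integrating I(0) back through the number density recovers the
        bound-surfactant concentration to machine precision."""
        Rcore, eps, D = 22.7, 0.60, 5.5
        C_total, C_free = 10.0, 2.0
        I0 = micelle_intensity_absolute(
            np.array([1e-9]), Rcore, eps, D, C_total, C_free, contrasts
        )[0]
        k1, k2, _ = complex_contrasts(Rcore, eps, D, 0.0, contrasts)
        n_agg = aggregation_number(Rcore, eps, contrasts.v_chain)
        n = I0 / (k1 + k2) ** 2
        assert n * n_agg / PER_MM_PER_CM3 == pytest.approx(
            C_total - C_free, rel=1e-10
        )


class TestGaussianChainPrefactor:
    def test_monomeric_blg_value(self, contrasts):
        """2 mg/mL of an 18.3 kDa monomer with the standard protein
        contrast gives ~0.0244 1/cm forward scattering."""
        I0 = gaussian_chain_prefactor(
            2.0, contrasts.protein_mass, contrasts.drho_m_protein
        )
        assert I0 == pytest.approx(0.0244, rel=0.02)

    def test_linearity_and_zero(self, contrasts):
        one = gaussian_chain_prefactor(1.0, 18300.0, 2.0e10)
        two = gaussian_chain_prefactor(2.0, 18300.0, 2.0e10)
        assert two == pytest.approx(2 * one, rel=1e-12)
        assert gaussian_chain_prefactor(0.0, 18300.0, 2.0e10) == 0.0


class TestContrastSetConfig:
    def test_overrides_apply(self):
        cs = ContrastSet.from_config({"v_chain": 360.0})
        assert cs.v_chain == 360.0

    def test_defaults_complete(self, contrasts):
        assert contrasts.v_protein > 0
        assert contrasts.b_protein > 0
        assert contrasts.protein_mass == 18300.0
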