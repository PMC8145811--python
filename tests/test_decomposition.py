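import numpy as np
import pytest

from saxsflow.composition import ContrastSet, gaussian_chain_prefactor
from saxsflow.curves import ScatteringCurve
from saxsflow.decomposition import (
    BasisSet,
    RgSchedule,
    ScaleFactors,
    decompose_frame,
    decompose_series,
)
from saxsflow.models import GaussianChainParams, gaussian_chain_intensity
from saxsflow.synthetic import (
    make_refolding_basis,
    refolding_scenario_for,
    simulate_refolding_series,
)


@pytest.fixture(scope="module")
def basis():
    sc = refolding_scenario_for("chi045", seed=0)
    cs = ContrastSet.from_config()
    curves = make_refolding_basis(sc, cs)
    I0 = gaussian_chain_prefactor(sc.c_protein, cs.protein_mass, cs.drho_m_protein)
    return BasisSet(
        complex=curves["complex"],
        micelle=curves["micelle"],
        native=curves["native"],
        I0_chain=I0,
    )


def _frame(basis, a1, a2, a3, a4, a5=0.0, rg=30.0, noise=0.0, seed=0):
    q = basis.complex.q
    I4 = gaussian_chain_intensity(GaussianChainParams(Rg=rg, I0=basis.I0_chain), q)
    I = a1 * basis.complex.I + a2 * basis.micelle.I + a3 * basis.native.I + a4 * I4 + a5
    sigma = np.maximum(0.01 * np.abs(I), 1e-30)
    if noise > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.standard_normal(I.shape) * noise * np.abs(I)
    return ScatteringCurve(q=q, I=I, sigma=sigma, time_s=1.0)


class TestScaleFactors:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conservation"):
            ScaleFactors(a1=0.5, a2=1.0, a3=0.3, a4=0.3, a5=0.0)
        ScaleFactors(a1=0.4, a2=1.0, a3=0.3, a4=0.3, a5=0.0)  # consistent


class TestDecomposeFrame:
    def test_pure_complex_identity(self, basis):
        frame = _frame(basis, 1.0, 0.0, 0.0, 0.0)
        scales, chi2 = decompose_frame(frame, basis)
        assert scales.a1 == pytest.approx(1.0, abs=1e-8)
        assert scales.a3 == pytest.approx(0.0, abs=1e-8)
        assert scales.a4 == pytest.approx(0.0, abs=1e-8)
        assert chi2 < 1e-12

    def test_zero_noise_mixture_exact(self, basis):
        """At zero noise the decomposition model is exact: truth scales are
        returned to at least 10 significant digits."""
        frame = _frame(basis, 0.5, 0.9, 0.3, 0.2, a5=1e-4)
        scales, _ = decompose_frame(frame, basis)
        assert scales.a1 == pytest.approx(0.5, rel=1e-10)
        assert scales.a2 == pytest.approx(0.9, rel=1e-10)
        assert scales.a3 == pytest.approx(0.3, rel=1e-10)
        assert scales.a4 == pytest.approx(0.2, rel=1e-10)
        assert scales.a5 == pytest.approx(1e-4, rel=1e-6)

    def test_noisy_mixture_recovered(self, basis):
        frame = _frame(basis, 0.5, 0.0, 0.3, 0.2, noise=0.01, seed=4)
        scales, _ = decompose_frame(frame, basis)
        assert scales.a1 == pytest.approx(0.5, abs=0.04)
        assert scales.a3 == pytest.approx(0.3, abs=0.04)
        assert scales.a4 == pytest.approx(0.2, abs=0.04)

    def test_background_absorbed(self, basis):
        frame = _frame(basis, 0.0, 0.0, 1.0, 0.0, a5=0.005)
        scales, _ = decompose_frame(frame, basis)
        assert scales.a3 == pytest.approx(1.0, rel=1e-8)
        assert scales.a5 == pytest.approx(0.005, rel=1e-6)

    def test_conservation_machine_precision(self, basis):
        frame = _frame(basis, 0.6, 0.5, 0.25, 0.15, noise=0.02, seed=9)
        scales, _ = decompose_frame(frame, basis)
        assert scales.a1 + scales.a3 + scales.a4 == pytest.approx(1.0, abs=1e-14)

    def test_rescaling_invariance(self, basis):
        """Multiplying frame and all bases by a common factor leaves the
        fractions unchanged."""
        frame = _frame(basis, 0.5, 0.8, 0.3, 0.2, noise=0.01, seed=2)
        scales1, _ = decompose_frame(frame, basis)
        fac = 7.3
        scaled_basis = BasisSet(
            complex=ScatteringCurve(
                q=basis.complex.q, I=fac * basis.complex.I,
                sigma=fac * basis.complex.sigma),
            micelle=ScatteringCurve(
                q=basis.micelle.q, I=fac * basis.micelle.I,
                sigma=fac * basis.micelle.sigma),
            native=ScatteringCurve(
                q=basis.native.q, I=fac * basis.native.I,
                sigma=fac * basis.native.sigma),
            I0_chain=fac * basis.I0_chain,
        )
        scaled_frame = ScatteringCurve(
            q=frame.q, I=fac * frame.I, sigma=fac * frame.sigma, time_s=frame.time_s
        )
        scales2, _ = decompose_frame(scaled_frame, scaled_basis)
        assert scales2.a1 == pytest.approx(scales1.a1, rel=1e-6)
        assert scales2.a3 == pytest.approx(scales1.a3, rel=1e-6)
        assert scales2.a4 == pytest.approx(scales1.a4, rel=1e-6)

    def test_two_step_chi2_calibration(self, basis):
        """With basis noise propagated (added to measurement variance) the
        reduced chi-square of correctly specified synthetic data is ~1;
        the frame-sigma-only first pass is biased upward."""
        rng = np.random.default_rng(11)
        a = (0.5, 0.8, 0.3, 0.2)
        q = basis.complex.q
        noisy_basis = BasisSet(
            complex=ScatteringCurve(
                q=q,
                I=basis.complex.I + rng.standard_normal(q.shape) * basis.complex.sigma,
                sigma=basis.complex.sigma),
            micelle=ScatteringCurve(
                q=q,
                I=basis.micelle.I + rng.standard_normal(q.shape) * basis.micelle.sigma,
                sigma=basis.micelle.sigma),
            native=ScatteringCurve(
                q=q,
                I=basis.native.I + rng.standard_normal(q.shape) * basis.native.sigma,
                sigma=basis.native.sigma),
            I0_chain=basis.I0_chain,
        )
        chis_two, chis_one = [], []
        for seed in range(5):
            frame = _frame(basis, *a, noise=0.01, seed=100 + seed)
            _, chi2_two = decompose_frame(
                frame, noisy_basis, include_measurement_sigma=True
            )
            # frame-sigma-only chi-square: residual vs noisy basis weighted
            # by the frame errors alone
            scales, _ = decompose_frame(frame, noisy_basis)
            model = (
                scales.a1 * noisy_basis.complex.I
                + scales.a2 * noisy_basis.micelle.I
                + scales.a3 * noisy_basis.native.I
                + scales.a4 * gaussian_chain_intensity(
                    GaussianChainParams(Rg=30.0, I0=basis.I0_chain), q)
                + scales.a5
            )
            chi_one = np.sum(((frame.I - model) / frame.sigma) ** 2) / (len(q) - 4)
            chis_two.append(chi2_two)
            chis_one.append(chi_one)
        assert 0.7 < np.mean(chis_two) < 1.4
        assert np.mean(chis_one) > np.mean(chis_two) * 1.3

    def test_no_protein_signal_flagged(self, basis):
        frame = _frame(basis, 0.0, 1.0, 0.0, 0.0)
        # remove the forced complex contribution: an all-micelle frame is
        # inconsistent with mass conservation and flagged degenerate
        scales, _ = decompose_frame(frame, basis)
        assert scales.a2 > 0.5
        # conservation still forces a1 + a3 + a4 = 1
        assert scales.a1 + scales.a3 + scales.a4 == pytest.approx(1.0, abs=1e-12)

    def test_resampling_onto_frame_grid(self, basis):
        q_frame = basis.complex.q[::2]
        I = np.interp(q_frame, basis.complex.q, basis.complex.I)
        frame = ScatteringCurve(q=q_frame, I=I, sigma=np.maximum(0.01 * I, 1e-30))
        scales, _ = decompose_frame(frame, basis)
        assert scales.a1 == pytest.approx(1.0, abs=1e-4)


class TestDecomposeSeries:
    def test_recovers_generator_fractions(self):
        sim = simulate_refolding_series(refolding_scenario_for("chi045", seed=5, n_frames=20))
        cs = ContrastSet.from_config()
        I0 = gaussian_chain_prefactor(2.0, cs.protein_mass, cs.drho_m_protein)
        basis = BasisSet(
            complex=sim.basis["complex"], micelle=sim.basis["micelle"],
            native=sim.basis["native"], I0_chain=I0,
        )
        table = decompose_series(sim.curves, basis, rg_schedule=30.0)
        merged = table.merge(sim.truth, on="time_s", suffixes=("_fit", "_true"))
        for col in ("a1", "a3", "a4"):
            assert np.max(np.abs(merged[f"{col}_fit"] - merged[f"{col}_true"])) < 0.05

    def test_rg_schedule_applied(self):
        sched = RgSchedule(rg=30.0, early_rg=40.0, early_until_s=0.5)
        assert sched(0.01) == 40.0
        assert sched(2.0) == 30.0
        assert sched(None) == 30.0
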