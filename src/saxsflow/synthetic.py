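"""Synthetic stopped-flow data with the statistical structure the analysis assumes.

No experimental curves are deposited with the study this package models,
so every pipeline stage is exercised on synthetic series that emulate the
measurement design: log-spaced frame times starting at the ~4 ms
instrument deadtime, absolute-scale model intensities, multiplicative
Gaussian noise that grows toward high q as counting statistics worsen,
and machine-readable truth tables so recovery tests never hard-code
expected values.

Unfolding series: the displaced-core model parameters relax exponentially
from an initial clustered, asymmetric state toward the equilibrium end
state, p(t) = p_end + (p0 - p_end)·2^(-t/t_half).

Refolding series: each frame is a mass-conserving mixture
a1·I_complex + a2·I_micelle + a3·I_native + a4·I_chain with a1+a3+a4 = 1;
a burst fraction of complexes converts to unfolded coil within the
deadtime, the coil folds to native on an intermediate timescale and the
remaining complexes convert slowly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import (
    ContrastSet,
    SolutionComposition,
    complex_intensity_absolute,
    gaussian_chain_prefactor,
    max_npro,
    micelle_intensity_absolute,
)
from .curves import ScatteringCurve, write_curve, write_series
from .kinetics import LN2, ExponentialFit, KineticTrace
from .models import GaussianChainParams, gaussian_chain_intensity
from .presets import REFOLDING_PRESETS, UNFOLDING_PRESETS, UnfoldingPreset
from .structures import debye_intensity, synthetic_dimer, synthetic_globule

DEFAULT_Q = np.geomspace(0.005, 0.4, 300)  # 1/Å
DEADTIME_S = 0.004


@dataclass
class NoiseModel:
    """sigma(q) = f_rel * I(q) * (1 + (q/q_c)^m): counts fall toward high q."""

    f_rel: float = 0.01
    q_c: float = 0.2   # 1/Å
    m: float = 2.0

    def sigma(self, q: np.ndarray, I: np.ndarray) -> np.ndarray:
        return self.f_rel * np.abs(I) * (1.0 + (q / self.q_c) ** self.m)


def add_noise(
    curve: ScatteringCurve, noise: NoiseModel | None = None, seed: int | None = None
) -> ScatteringCurve:
    """Gaussian noise drawn per point with the model sigma; sigma column
    carries the true sigma. ``f_rel=0`` returns the curve unchanged."""
    noise = noise or NoiseModel()
    if noise.f_rel == 0:
        return curve
    rng = np.random.default_rng(seed)
    sigma = noise.sigma(curve.q, curve.I)
    I = curve.I + rng.standard_normal(curve.I.shape) * sigma
    return ScatteringCurve(
        q=curve.q, I=I, sigma=np.maximum(sigma, 1e-30),
        time_s=curve.time_s, label=curve.label,
    )


def frame_times(
    n_frames: int, t_max: float, deadtime_s: float = DEADTIME_S
) -> np.ndarray:
    """Log-spaced mid-exposure frame times from the deadtime to t_max."""
    return np.geomspace(deadtime_s, t_max, n_frames)


# ---------------------------------------------------------------------------
# unfolding


@dataclass
class UnfoldingScenario:
    """One stopped-flow unfolding experiment.

    Defaults are the 10.5 mM SDS condition: end state from the equilibrium
    fit, initial state with strong clustering (several proteins and
    complexes per cluster), a maximal core offset, and relaxation
    half-times matching the fast SAXS phases (proteins-per-complex ~0.4 s,
    core offset ~1.4 s).
    """

    preset: UnfoldingPreset = field(
        default_factory=lambda: UNFOLDING_PRESETS["sds10.5"]
    )
    Npro0: float = 4.0
    Nmic0: float = 6.0
    s0: float | None = None          # default: 0.8 * Dhead (strongly displaced)
    Dhead0: float | None = None      # only the 4.1 mM condition relaxes Dhead
    Rcore0: float | None = None
    half_times: dict[str, float] = field(
        default_factory=lambda: {"Npro": 0.36, "s": 1.38, "Nmic": 0.36}
    )
    n_frames: int = 40
    t_max: float = 759.0
    deadtime_s: float = DEADTIME_S
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    q: np.ndarray = field(default_factory=lambda: DEFAULT_Q.copy())

    def truth_at(self, t: float) -> dict[str, float]:
        p = self.preset
        # generation mirrors the series-fit protocol: Dhead relaxes toward
        # the value locked during series fits (the 4.1 mM condition instead
        # relaxes Dhead and Rcore from larger initial values)
        Dhead_end = p.series_Dhead if p.series_Dhead is not None else p.Dhead

        def relax(p0, p_end, key):
            th = self.half_times.get(key)
            if p0 is None or th is None:
                return p_end
            return p_end + (p0 - p_end) * np.exp(-t * LN2 / th)

        Dhead = relax(self.Dhead0, Dhead_end, "Dhead")
        s0 = self.s0 if self.s0 is not None else 0.8 * Dhead_end
        return {
            "Rcore": relax(self.Rcore0, p.Rcore, "Rcore"),
            "eps": p.eps,
            "Dhead": Dhead,
            "s": min(relax(s0, p.s, "s"), Dhead),
            "Npro": relax(self.Npro0, p.Npro, "Npro"),
            "Nmic": max(relax(self.Nmic0, p.Nmic, "Nmic"), 1.0),
        }


@dataclass
class SimulatedSeries:
    curves: list[ScatteringCurve]
    truth: pd.DataFrame
    basis: dict[str, ScatteringCurve] | None = None
    manifest: Path | None = None


def simulate_unfolding_series(
    sc: UnfoldingScenario,
    cs: ContrastSet | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedSeries:
    """Generate a noisy unfolding frame series plus its truth table.

    Each frame is the absolute-scale displaced-core model at the relaxed
    parameters for that frame's mid-time. With ``out_dir`` set, frames,
    manifest and ``truth.csv`` are written there.
    """
    cs = cs or ContrastSet.from_config()
    times = frame_times(sc.n_frames, sc.t_max, sc.deadtime_s)
    rng = np.random.default_rng(sc.seed)
    curves, rows = [], []
    for t in times:
        truth = sc.truth_at(t)
        # shells cannot be overfilled: cap Npro at the geometric capacity
        cap = 0.95 * max_npro(truth["Rcore"], truth["eps"], truth["Dhead"], cs)
        truth["Npro"] = min(truth["Npro"], cap)
        comp = SolutionComposition(
            c_protein=sc.preset.c_protein,
            C_SDS_total=sc.preset.C_SDS_total,
            C_SDS_free=sc.preset.C_SDS_free,
            Npro=truth["Npro"],
            Nmic=truth["Nmic"],
        )
        I = complex_intensity_absolute(
            sc.q,
            Rcore=truth["Rcore"],
            eps=truth["eps"],
            Dhead=truth["Dhead"],
            s=truth["s"],
            comp=comp,
            cs=cs,
            Dmic=sc.preset.Dmic,
        )
        clean = ScatteringCurve(
            q=sc.q, I=I, sigma=np.maximum(sc.noise.sigma(sc.q, I), 1e-30),
            time_s=float(t), label=f"unfolding {sc.preset.name}",
        )
        noisy = add_noise(clean, sc.noise, seed=int(rng.integers(2**31)))
        curves.append(noisy)
        rows.append({"time_s": float(t), **truth})
    truth_df = pd.DataFrame(rows)
    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest = write_series(curves, out_dir, deadtime_s=sc.deadtime_s)
        truth_df.to_csv(out_dir / "truth.csv", index=False)
    return SimulatedSeries(curves=curves, truth=truth_df, manifest=manifest)


# ---------------------------------------------------------------------------
# refolding


@dataclass
class RefoldingScenario:
    """One stopped-flow refolding experiment (complexes + C12E8).

    Defaults are the chi_SDS = 0.45 condition: roughly half the complexes
    are disrupted to unfolded coil within the deadtime, the coil folds
    with an intermediate half-time and the surviving complexes convert
    slowly (half-time ~1110 s). Fractions conserve protein mass at all
    times by construction.
    """

    chi_sds: float = 0.45
    burst_coil: float = 0.50         # coil fraction at t -> 0
    t_half_complex: float = 1110.0   # s, complex -> native
    t_half_coil: float = 242.0       # s, coil -> native
    rg_chain: float = 30.0           # Å
    rg_early: float | None = None    # optional larger Rg before rg_early_until_s
    rg_early_until_s: float = 0.0
    micelle_scale: float = 1.0       # a2, constant over the series
    n_frames: int = 60
    t_max: float = 3000.0
    deadtime_s: float = DEADTIME_S
    noise: NoiseModel = field(default_factory=NoiseModel)
    c_protein: float = 2.0           # mg/mL
    seed: int = 0
    q: np.ndarray = field(default_factory=lambda: DEFAULT_Q.copy())

    def fractions_at(self, t: float) -> tuple[float, float, float]:
        """(a1 complex, a3 native, a4 coil); a1 + a3 + a4 = 1 exactly."""
        a1_0 = 1.0 - self.burst_coil
        a1 = a1_0 * np.exp(-t * LN2 / self.t_half_complex)
        a4 = self.burst_coil * np.exp(-t * LN2 / self.t_half_coil)
        a3 = 1.0 - a1 - a4
        return float(a1), float(a3), float(a4)


def _mixed_micelle_contrasts(cs: ContrastSet, chi: float) -> ContrastSet:
    """Contrast table whose 'sds' head is the chi-weighted SDS/C12E8 mix."""
    v = chi * cs.v_head_sds + (1 - chi) * cs.v_head_c12e8
    b = chi * cs.b_head_sds + (1 - chi) * cs.b_head_c12e8
    return dc_replace(cs, v_head_sds=v, b_head_sds=b)


def make_refolding_basis(
    sc: RefoldingScenario, cs: ContrastSet | None = None
) -> dict[str, ScatteringCurve]:
    """Noise-free basis curves of the pure species on the scenario grid.

    complex: displaced-core bLG-SDS complex at the refolding SDS load;
    micelle: mixed SDS/C12E8 micelle at the series' overall composition;
    native: Debye curve of a 77:23 dimer:monomer mixture of synthetic
    globular bead models at the protein concentration.
    """
    cs = cs or ContrastSet.from_config()
    q = sc.q
    end = UNFOLDING_PRESETS["sds10.5"]
    comp = SolutionComposition(
        c_protein=sc.c_protein, C_SDS_total=8.5, C_SDS_free=1.0,
        Npro=end.Npro, Nmic=1.0,
    )
    I_complex = complex_intensity_absolute(
        q, Rcore=end.Rcore, eps=end.eps, Dhead=end.Dhead, s=end.s,
        comp=comp, cs=cs,
    )
    mixed_cs = _mixed_micelle_contrasts(cs, sc.chi_sds)
    C_surf = 8.5 / max(sc.chi_sds, 1e-9)  # total surfactant at this chi
    I_micelle = micelle_intensity_absolute(
        q, Rcore=22.0, eps=0.62, Dhead=10.0,
        C_total=C_surf, C_free=2.0, cs=mixed_cs,
    )
    mono = synthetic_globule(seed=1)
    dim = synthetic_dimer(seed=1)
    I_native = 0.23 * debye_intensity(mono, q, c_mg_ml=sc.c_protein) + (
        0.77 * debye_intensity(dim, q, c_mg_ml=sc.c_protein)
    )
    return {
        "complex": ScatteringCurve(q=q, I=I_complex, sigma=np.maximum(1e-30, 0.01 * I_complex), label="complex basis"),
        "micelle": ScatteringCurve(q=q, I=I_micelle, sigma=np.maximum(1e-30, 0.01 * I_micelle), label="mixed micelle basis"),
        "native": ScatteringCurve(q=q, I=I_native, sigma=np.maximum(1e-30, 0.01 * I_native), label="native basis"),
    }


def simulate_refolding_series(
    sc: RefoldingScenario,
    cs: ContrastSet | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedSeries:
    """Generate a refolding series, its basis curves and the truth table.

    Basis curves are re-measured with their own noise realisations and
    carry sigma columns; frames are the mass-conserving mixtures plus
    frame noise. The truth table holds the generating fractions.
    """
    cs = cs or ContrastSet.from_config()
    rng = np.random.default_rng(sc.seed)
    clean_basis = make_refolding_basis(sc, cs)
    noisy_basis = {
        name: add_noise(c, sc.noise, seed=int(rng.integers(2**31)))
        for name, c in clean_basis.items()
    }
    I0_chain = gaussian_chain_prefactor(
        sc.c_protein, cs.protein_mass, cs.drho_m_protein
    )
    times = frame_times(sc.n_frames, sc.t_max, sc.deadtime_s)
    curves, rows = [], []
    for t in times:
        a1, a3, a4 = sc.fractions_at(t)
        rg = (
            sc.rg_early
            if (sc.rg_early is not None and t < sc.rg_early_until_s)
            else sc.rg_chain
        )
        I_chain = gaussian_chain_intensity(
            GaussianChainParams(Rg=rg, I0=I0_chain), sc.q
        )
        I = (
            a1 * clean_basis["complex"].I
            + sc.micelle_scale * clean_basis["micelle"].I
            + a3 * clean_basis["native"].I
            + a4 * I_chain
        )
        clean = ScatteringCurve(
            q=sc.q, I=I, sigma=np.maximum(sc.noise.sigma(sc.q, I), 1e-30),
            time_s=float(t), label=f"refolding chi={sc.chi_sds}",
        )
        curves.append(add_noise(clean, sc.noise, seed=int(rng.integers(2**31))))
        rows.append(
            {"time_s": float(t), "a1": a1, "a2": sc.micelle_scale,
             "a3": a3, "a4": a4, "rg": rg}
        )
    truth_df = pd.DataFrame(rows)
    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest = write_series(curves, out_dir, deadtime_s=sc.deadtime_s)
        truth_df.to_csv(out_dir / "truth.csv", index=False)
        for name, c in noisy_basis.items():
            write_curve(c, out_dir / f"basis_{name}.dat")
    return SimulatedSeries(
        curves=curves, truth=truth_df, basis=noisy_basis, manifest=manifest
    )


def refolding_scenario_for(chi_key: str, **overrides) -> RefoldingScenario:
    """Scenario preconfigured for one of the two studied mole fractions.

    ``chi_key`` is "chi045" (just enough C12E8) or "chi030" (excess);
    the complex-conversion half-time and burst fraction follow the
    condition (refolding is 3-6x faster and disruption larger in excess
    C12E8).
    """
    p = REFOLDING_PRESETS[chi_key]
    defaults = dict(
        chi_sds=p["chi_sds"],
        t_half_complex=p["t_half_complex"],
        t_half_coil=242.0 if chi_key == "chi045" else 101.0,
        burst_coil=0.50 if chi_key == "chi045" else 0.65,
    )
    defaults.update(overrides)
    return RefoldingScenario(**defaults)


# ---------------------------------------------------------------------------
# kinetic traces


def simulate_kinetic_trace(
    truth: ExponentialFit,
    t: np.ndarray,
    noise_rel: float = 0.01,
    seed: int | None = None,
) -> tuple[KineticTrace, ExponentialFit]:
    """Noisy trace from exponential-decay truth parameters; returns
    (trace, truth). Noise is Gaussian with sigma = noise_rel * signal span."""
    t = np.asarray(t, dtype=float)
    y = truth.predict(t)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_rel * float(np.ptp(y) if np.ptp(y) > 0 else 1.0)
        y = y + rng.standard_normal(t.shape) * sigma
        return KineticTrace(t=t, y=y, sigma=np.full_like(t, sigma)), truth
    return KineticTrace(t=t, y=y), truth


def trace_truth_from_halftimes(
    halftimes: tuple[float, ...],
    amplitudes: tuple[float, ...],
    offset: float = 1.0,
) -> ExponentialFit:
    """Truth container from half-times (s) and amplitudes; rates = ln2/t12."""
    rates = np.array([LN2 / th for th in halftimes])
    order = np.argsort(rates)[::-1]
    return ExponentialFit(
        n=len(halftimes),
        amplitudes=np.asarray(amplitudes, float)[order],
        rates=rates[order],
        offset=offset,
        chi2_red=0.0,
    )
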