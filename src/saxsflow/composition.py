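"""Absolute-scale composition bookkeeping.

Converts chemistry — surfactant concentrations, molecular volumes and
scattering lengths — into the quantities the geometric models need: the
total excess scattering lengths ``k1`` (shell) and ``k2`` (core − shell),
particle number densities, micelle aggregation numbers and the water
content of the shell. Keeping all contrast constants in one overridable
table (``data/contrasts_default.json``) means no numeric constants hide in
model code.

Scattering lengths are electron-based: ``b = n_electrons · r_e`` with the
Thomson radius ``r_e = 2.8179403e-13 cm``; all absolute intensities come
out in 1/cm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .models import (
    DisplacedCoreShellParams,
    MicelleParams,
    RandomFlightParams,
    displaced_core_shell_intensity,
    eps_outer_from_core,
    random_flight_sf,
)

logger = logging.getLogger(__name__)

THOMSON_RADIUS_CM = 2.8179403e-13
AVOGADRO = 6.02214076e23
#: molecules per cm^3 at 1 mmol/L
PER_MM_PER_CM3 = AVOGADRO / 1e6


@dataclass
class ContrastSet:
    """Molecular volumes (Å³), scattering lengths (cm) and solvent density.

    ``drho_m_protein`` (cm/g) is the mass-specific excess scattering length
    of protein used for the Gaussian-chain forward-scattering prefactor.
    """

    v_chain: float
    v_head_sds: float
    v_head_c12e8: float
    v_protein: float
    b_chain: float
    b_head_sds: float
    b_head_c12e8: float
    b_protein: float
    rho_solvent: float
    protein_mass: float
    drho_m_protein: float

    def __post_init__(self) -> None:
        for name in ("v_chain", "v_head_sds", "v_head_c12e8", "v_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_config(cls, config: dict | str | Path | None = None) -> "ContrastSet":
        """Build from the shipped default table, optionally overridden.

        ``config`` may be a dict of overrides or a path to a JSON file with
        the same keys as ``data/contrasts_default.json``.
        """
        raw = json.loads(
            resources.files("saxsflow.data")
            .joinpath("contrasts_default.json")
            .read_text()
        )
        if config is not None:
            if isinstance(config, (str, Path)):
                config = json.loads(Path(config).read_text())
            raw.update(config)
        mass = raw["protein_mass_da"]
        v_protein = mass * raw["protein_vbar_cm3_per_g"] / AVOGADRO * 1e24  # Å³
        re = THOMSON_RADIUS_CM
        return cls(
            v_chain=raw["v_chain"],
            v_head_sds=raw["v_head_sds"],
            v_head_c12e8=raw["v_head_c12e8"],
            v_protein=v_protein,
            b_chain=raw["electrons_chain"] * re,
            b_head_sds=raw["electrons_head_sds"] * re,
            b_head_c12e8=raw["electrons_head_c12e8"] * re,
            b_protein=raw["electrons_protein_per_da"] * mass * re,
            rho_solvent=raw["rho_solvent"],
            protein_mass=mass,
            drho_m_protein=raw["drho_m_protein"],
        )


@dataclass
class SolutionComposition:
    """What is in the cuvette, per litre and per complex."""

    c_protein: float = 2.0      # mg/mL
    C_SDS_total: float = 10.5   # mM
    C_SDS_free: float = 3.7     # mM
    C_C12E8: float = 0.0        # mM
    Npro: float = 1.0           # proteins per complex
    Nmic: float = 1.0           # complexes per cluster

    def __post_init__(self) -> None:
        if not 0 <= self.C_SDS_free <= self.C_SDS_total:
            raise ValueError("need 0 <= C_SDS_free <= C_SDS_total")
        if self.c_protein < 0:
            raise ValueError("c_protein must be >= 0")

    @property
    def C_SDS_bound(self) -> float:
        return self.C_SDS_total - self.C_SDS_free


def aggregation_number(Rcore: float, eps: float, v_chain: float) -> float:
    """Surfactant molecules per micelle: core volume / single-chain volume.

    N_agg = (4π/3)·eps·Rcore³ / v_chain, with Rcore the equatorial core
    radius and eps the axis ratio of the spheroidal core.
    """
    if Rcore <= 0 or eps <= 0 or v_chain <= 0:
        raise ValueError("inputs must be positive")
    return (4.0 * np.pi / 3.0) * eps * Rcore**3 / v_chain


def chi_sds(C_SDS: float, C_C12E8: float) -> float:
    """SDS mole fraction among total surfactant, χ = C_SDS/(C_SDS + C_C12E8)."""
    if C_SDS < 0 or C_C12E8 < 0:
        raise ValueError("concentrations must be nonnegative")
    total = C_SDS + C_C12E8
    if total == 0:
        raise ValueError("both surfactant concentrations are zero")
    return C_SDS / total


def complex_contrasts(
    Rcore: float,
    eps: float,
    Dshell: float,
    Npro: float,
    cs: ContrastSet,
    head: str = "sds",
) -> tuple[float, float, float]:
    """Shell/core excess scattering lengths and shell water fraction.

    The core (volume ``v2 = 4π/3·eps·Rcore³``) holds exactly the alkyl
    chains of ``N_agg = v2/v_chain`` surfactants, so its contrast is that
    of pure chain. The shell holds the ``N_agg`` head groups, ``Npro``
    proteins and filling water; its mean excess density comes from
    distributing their excess scattering length uniformly over the shell
    volume (water carries zero excess and only fills volume).

    Returns ``(k1, k2, water_fraction)`` with ``k1 = v1·Δρ1`` and
    ``k2 = v2·(Δρ2 − Δρ1)`` in cm.

    Raises ``ValueError`` if heads + protein overfill the shell (negative
    water volume): geometry inconsistent with composition.
    """
    v_head = {"sds": cs.v_head_sds, "c12e8": cs.v_head_c12e8}[head]
    b_head = {"sds": cs.b_head_sds, "c12e8": cs.b_head_c12e8}[head]
    v2 = (4.0 * np.pi / 3.0) * eps * Rcore**3  # Å³
    n_agg = v2 / cs.v_chain
    eps1 = eps_outer_from_core(Rcore, eps, Dshell)
    R1 = Rcore + Dshell
    v1 = (4.0 * np.pi / 3.0) * eps1 * R1**3
    v_shell = v1 - v2
    v_occupied = n_agg * v_head + Npro * cs.v_protein
    v_water = v_shell - v_occupied
    if v_water < 0:
        raise ValueError(
            "geometry inconsistent with composition: shell volume "
            f"{v_shell:.0f} Å³ < heads+protein {v_occupied:.0f} Å³"
        )
    A3_TO_CM3 = 1e-24
    rho_s = cs.rho_solvent
    # excess scattering lengths (cm) of the occupants
    db_head = b_head - v_head * A3_TO_CM3 * rho_s
    db_protein = cs.b_protein - cs.v_protein * A3_TO_CM3 * rho_s
    db_chain = cs.b_chain - cs.v_chain * A3_TO_CM3 * rho_s
    drho1 = (n_agg * db_head + Npro * db_protein) / (v_shell * A3_TO_CM3)
    drho2 = n_agg * db_chain / (v2 * A3_TO_CM3)
    k1 = v1 * A3_TO_CM3 * drho1
    k2 = v2 * A3_TO_CM3 * (drho2 - drho1)
    return k1, k2, v_water / v_shell


def max_npro(Rcore: float, eps: float, Dshell: float, cs: ContrastSet,
             head: str = "sds") -> float:
    """Largest Npro the shell can host with nonnegative water volume."""
    v_head = {"sds": cs.v_head_sds, "c12e8": cs.v_head_c12e8}[head]
    v2 = (4.0 * np.pi / 3.0) * eps * Rcore**3
    n_agg = v2 / cs.v_chain
    eps1 = eps_outer_from_core(Rcore, eps, Dshell)
    v1 = (4.0 * np.pi / 3.0) * eps1 * (Rcore + Dshell) ** 3
    return max((v1 - v2 - n_agg * v_head) / cs.v_protein, 0.0)


def number_density(comp: SolutionComposition, N_agg: float) -> float:
    """Cluster number density (cm⁻³) from the bound-surfactant budget.

    All bound surfactant sits in complexes of ``N_agg`` molecules grouped
    ``Nmic`` per cluster: n = C_bound[mM]·6.022e17 / (N_agg·Nmic). Use
    :func:`implied_protein_concentration` to compare the fitted ``Npro``
    against the pipetted ``c_protein`` (the model fits Npro freely).
    """
    if N_agg <= 0:
        raise ValueError("N_agg must be > 0")
    return comp.C_SDS_bound * PER_MM_PER_CM3 / (N_agg * comp.Nmic)


def implied_protein_concentration(
    comp: SolutionComposition, N_agg: float, protein_mass: float
) -> float:
    """Protein concentration (mg/mL) implied by the fitted Npro — diagnostic."""
    n_cluster = number_density(comp, N_agg)
    n_protein = n_cluster * comp.Nmic * comp.Npro  # per cm³
    return n_protein * protein_mass / AVOGADRO * 1e3  # g/cm³ → mg/mL


def gaussian_chain_prefactor(c_protein: float, mass: float, drho_m: float) -> float:
    """Absolute forward scattering of an ideal monomer solution, 1/cm.

    I(0) = c·M·Δρ_m²/N_A with c in g/cm³ (mg/mL input is divided by 1000),
    M in Da and Δρ_m the mass-specific excess scattering length in cm/g.
    """
    if c_protein < 0 or mass <= 0 or drho_m <= 0:
        raise ValueError("inputs must be positive (c_protein may be 0)")
    c = c_protein * 1e-3  # g/cm³
    return c * mass * drho_m**2 / AVOGADRO


def complex_intensity_absolute(
    q,
    Rcore: float,
    eps: float,
    Dhead: float,
    s: float,
    comp: SolutionComposition,
    cs: ContrastSet,
    Dmic: float = 50.0,
    head: str = "sds",
    variant: str = "amplitude",
    order: int = 76,
):
    """Absolute intensity (1/cm) of a solution of (clustered) complexes.

    Assembles the full absolute-scale model the frame fits use:
    contrast weights from the composition, the displaced-core form factor,
    the random-flight cluster structure factor (``comp.Nmic``) and the
    cluster number density: ``I(q) = n·P(q)·S(q)``.
    """
    k1, k2, _ = complex_contrasts(Rcore, eps, Dhead, comp.Npro, cs, head=head)
    p = DisplacedCoreShellParams(R2=Rcore, eps2=eps, Dshell=Dhead, s=s, k1=k1, k2=k2)
    P = displaced_core_shell_intensity(p, q, order=order, variant=variant)
    if comp.Nmic > 1:
        S = random_flight_sf(RandomFlightParams(Nmic=comp.Nmic, Dmic=Dmic), q)
    else:
        S = 1.0
    n_agg = aggregation_number(Rcore, eps, cs.v_chain)
    n = number_density(comp, n_agg)
    return n * P * S


def micelle_intensity_absolute(
    q,
    Rcore: float,
    eps: float,
    Dhead: float,
    C_total: float,
    C_free: float,
    cs: ContrastSet,
    head: str = "sds",
    order: int = 76,
):
    """Absolute intensity (1/cm) of a pure (protein-free) micelle solution."""
    k1, k2, _ = complex_contrasts(Rcore, eps, Dhead, 0.0, cs, head=head)
    p = MicelleParams(Rcore=Rcore, eps=eps, Dhead=Dhead, k1=k1, k2=k2)
    P = displaced_core_shell_intensity(p.as_displaced(), q, order=order)
    n_agg = aggregation_number(Rcore, eps, cs.v_chain)
    n = (C_total - C_free) * PER_MM_PER_CM3 / n_agg
    return n * P
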