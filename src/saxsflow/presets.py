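"""End-state parameter presets and series-fit protocols.

One preset per unfolding condition (final SDS concentration after 1:1
mixing) holding the equilibrium displaced-core geometry, the composition
and the locking protocol used when fitting the full stopped-flow series:
the micelle spacing ``Dmic`` is fixed at 50 Å everywhere, the axis ratio
``eps`` at its end-state value, and the head thickness ``Dhead`` at 15 Å;
only the 4.1 mM condition frees ``Dhead`` and ``Rcore``, which relax from
larger initial values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import SolutionComposition


@dataclass(frozen=True)
class UnfoldingPreset:
    """Equilibrium end state + series protocol for one SDS concentration."""

    name: str
    Dhead: float          # Å, end-state shell thickness
    Rcore: float          # Å, end-state core equatorial radius
    eps: float            # core axis ratio (locked in series fits)
    Nmic: float           # end-state complexes per cluster
    Dmic: float           # Å, cluster spacing (locked)
    C_SDS_total: float    # mM
    C_SDS_free: float     # mM
    Npro: float           # end-state proteins per complex
    s: float              # Å, end-state core offset
    series_lock: tuple[str, ...] = ("eps", "Nmic", "Dhead")
    series_Dhead: float | None = None  # Å, lock value during series fits
    c_protein: float = 2.0  # mg/mL, final measured protein concentration

    def composition(self) -> SolutionComposition:
        return SolutionComposition(
            c_protein=self.c_protein,
            C_SDS_total=self.C_SDS_total,
            C_SDS_free=self.C_SDS_free,
            Npro=self.Npro,
            Nmic=self.Nmic,
        )


UNFOLDING_PRESETS: dict[str, UnfoldingPreset] = {
    "sds2.0": UnfoldingPreset(
        name="sds2.0", Dhead=15.0, Rcore=7.6, eps=3.4, Nmic=1.15, Dmic=50.0,
        C_SDS_total=2.0, C_SDS_free=0.7, Npro=1.96, s=7.4,
        # Dhead locked at the end-state value: with the default volume table
        # a thinner 10 Å shell cannot host ~2 proteins per complex
        series_lock=("eps", "Dhead"), series_Dhead=15.0,
    ),
    "sds4.1": UnfoldingPreset(
        name="sds4.1", Dhead=13.2, Rcore=8.8, eps=3.4, Nmic=1.0, Dmic=50.0,
        C_SDS_total=4.1, C_SDS_free=1.8, Npro=1.48, s=3.2,
        # the special case: Dhead and Rcore stay free and relax downward
        series_lock=("eps",), series_Dhead=None,
    ),
    "sds7.3": UnfoldingPreset(
        name="sds7.3", Dhead=10.2, Rcore=11.5, eps=2.1, Nmic=1.0, Dmic=50.0,
        C_SDS_total=7.3, C_SDS_free=2.6, Npro=0.97, s=2.1,
        series_lock=("eps", "Dhead"), series_Dhead=15.0,
    ),
    "sds10.5": UnfoldingPreset(
        name="sds10.5", Dhead=10.1, Rcore=13.7, eps=1.8, Nmic=1.0, Dmic=50.0,
        C_SDS_total=10.5, C_SDS_free=3.7, Npro=0.98, s=1.9,
        series_lock=("eps", "Dhead"), series_Dhead=15.0,
    ),
}

#: fitted micelle geometries of the pure surfactants (long-axis core radius,
#: axis ratio, head-group shell thickness)
MICELLE_PRESETS: dict[str, dict[str, float]] = {
    "sds": {"Rcore": 22.7, "eps": 0.60, "Dhead": 5.5},
    "c12e8": {"Rcore": 21.0, "eps": 0.64, "Dhead": 15.0},
}

#: refolding conditions: SDS mole fraction after adding C12E8 to 17.0 mM SDS
#: (final concentrations after 1:1 mixing: 8.5 mM SDS, and C12E8 such that
#: chi_SDS is just sufficient (0.45) or in excess (0.30) for refolding)
REFOLDING_PRESETS: dict[str, dict[str, float]] = {
    "chi045": {"chi_sds": 0.45, "C_SDS": 8.5, "C_C12E8": 10.4, "t_half_complex": 1110.0},
    "chi030": {"chi_sds": 0.30, "C_SDS": 8.5, "C_C12E8": 19.8, "t_half_complex": 385.0},
}
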