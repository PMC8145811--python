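"""Scattering models for protein–surfactant complexes.

The central model is a core–shell ellipsoid of revolution whose core centre
may be displaced a distance ``s`` perpendicular to the symmetry axis,
describing a surfactant micelle with protein bound asymmetrically on one
side. Supporting models: the concentric core–shell ellipsoid (free
micelles), a random-flight structure factor for clusters of complexes, and
the Debye Gaussian-chain form factor for unfolded protein.

Geometry and amplitudes
-----------------------
With ``Φ(x) = 3(sin x − x cos x)/x³`` the normalised homogeneous-ellipsoid
amplitude and ``r_i(θ)² = R_i²(sin²θ + ε_i² cos²θ)`` the effective radius of
ellipsoid *i* at polar angle θ, the orientational amplitude of the displaced
model is

    A(q, θ) = k1·Φ(q·r1(θ)) + k2·Φ(q·r2(θ))·J0(q·s·sinθ)

where index 1 is the outer surface (shell) and 2 the core, ``k1 = v1·Δρ1``
and ``k2 = v2·(Δρ2 − Δρ1)`` are total excess scattering lengths (cm), and
J0 is the zeroth-order Bessel function carrying the in-plane core offset.
The form factor is the sphere-average ``P(q) = ∫₀^{π/2} A²(q,θ) sinθ dθ``
(the ``sinθ`` weight integrates to 1 on [0, π/2]), so ``P(0) = (k1+k2)²``.

This "amplitude form" squares the azimuthally averaged amplitude, so the
core self-term carries J0². The exact azimuthal average of the intensity
keeps J0 only in the cross term; it is available via ``variant="exact"``.

Shell uniformity: requiring the shell thickness to equal ``Dshell`` on both
the equator and the pole ties the axis ratios together through
``ε2 = (ε1·R1 − Dshell)/(R1 − Dshell)``; :func:`eps_outer_from_core` inverts
this for the outer ratio given the core geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

__all__ = [
    "DisplacedCoreShellParams",
    "MicelleParams",
    "RandomFlightParams",
    "GaussianChainParams",
    "sphere_amplitude",
    "effective_radius",
    "eps_outer_from_core",
    "eps_core_from_outer",
    "displaced_core_shell_intensity",
    "concentric_core_shell_intensity",
    "random_flight_sf",
    "gaussian_chain_intensity",
]

#: default Gauss–Legendre order for the θ quadrature (spectral convergence)
DEFAULT_QUAD_ORDER = 76

#: below this argument Φ(x) switches to its Taylor series (cancellation)
_PHI_SERIES_CUTOFF = 1e-2


@dataclass
class DisplacedCoreShellParams:
    """Geometry and contrast weights of one displaced-core complex.

    Attributes
    ----------
    R2 : float
        Core equatorial radius, Å.
    eps2 : float
        Core axis ratio (polar/equatorial); >1 prolate, <1 oblate.
    Dshell : float
        Shell (head groups + protein + water) thickness, Å.
    s : float
        Offset of the core centre perpendicular to the symmetry axis, Å;
        must satisfy ``0 <= s <= R1 - R2``.
    k1, k2 : float
        Total excess scattering lengths (cm) of the shell term and the
        core-minus-shell term.
    """

    R2: float
    eps2: float
    Dshell: float
    s: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.R2 <= 0 or self.eps2 <= 0 or self.Dshell < 0:
            raise ValueError("R2, eps2 must be > 0 and Dshell >= 0")
        if not 0 <= self.s <= self.R1 - self.R2 + 1e-12:
            raise ValueError(
                f"core offset s={self.s:g} violates s <= R1 - R2 = "
                f"{self.R1 - self.R2:g}"
            )

    @property
    def R1(self) -> float:
        """Outer equatorial radius, Å."""
        return self.R2 + self.Dshell

    @property
    def eps1(self) -> float:
        """Outer axis ratio keeping the shell thickness uniform."""
        return eps_outer_from_core(self.R2, self.eps2, self.Dshell)


@dataclass
class MicelleParams:
    """Concentric core–shell ellipsoid (free micelle): displaced model, s = 0."""

    Rcore: float
    eps: float
    Dhead: float
    k1: float
    k2: float

    def as_displaced(self) -> DisplacedCoreShellParams:
        return DisplacedCoreShellParams(
            R2=self.Rcore, eps2=self.eps, Dshell=self.Dhead, s=0.0,
            k1=self.k1, k2=self.k2,
        )


@dataclass
class RandomFlightParams:
    """Random-flight cluster of complexes: mean multiplicity and spacing."""

    Nmic: float  # mean complexes per cluster, >= 1, may be non-integer
    Dmic: float  # centre-to-centre distance, Å

    def __post_init__(self) -> None:
        if self.Nmic < 1:
            raise ValueError("Nmic must be >= 1")
        if self.Dmic <= 0:
            raise ValueError("Dmic must be > 0")


@dataclass
class GaussianChainParams:
    """Debye Gaussian chain for unfolded protein."""

    Rg: float  # root-mean-square radius of gyration, Å
    I0: float  # absolute forward scattering, 1/cm

    def __post_init__(self) -> None:
        if self.Rg <= 0 or self.I0 <= 0:
            raise ValueError("Rg and I0 must be > 0")


def sphere_amplitude(x):
    """Normalised homogeneous-ellipsoid amplitude Φ(x) = 3(sin x − x cos x)/x³.

    Φ(0) = 1; |Φ| <= 1. A 3-term Taylor series is used below
    ``x = 1e-2`` to avoid catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = np.abs(x) < _PHI_SERIES_CUTOFF
    xs = x[small]
    # Φ(x) = 1 − x²/10 + x⁴/280 − x⁶/15120 + ...
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0 - xs**6 / 15120.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out[0] if scalar else out


def effective_radius(R, eps, theta):
    """Effective radius r(θ) = R·sqrt(sin²θ + ε²cos²θ) of a spheroid.

    θ = π/2 gives the equatorial radius R, θ = 0 the polar semi-axis ε·R.
    """
    s, c = np.sin(theta), np.cos(theta)
    return R * np.sqrt(s * s + eps * eps * c * c)


def eps_outer_from_core(R2, eps2, Dshell):
    """Outer axis ratio ε1 giving a uniform shell of thickness Dshell.

    Inverts ε2 = (ε1·R1 − Dshell)/(R1 − Dshell) with R1 = R2 + Dshell, so
    ε1 = (ε2·R2 + Dshell)/(R2 + Dshell).
    """
    return (eps2 * R2 + Dshell) / (R2 + Dshell)


def eps_core_from_outer(R1, eps1, Dshell):
    """Forward shell-uniformity relation ε2 = (ε1·R1 − Dshell)/(R1 − Dshell)."""
    return (eps1 * R1 - Dshell) / (R1 - Dshell)


def _gauss_theta(order: int):
    """Gauss–Legendre nodes/weights for ∫₀^{π/2} f(θ) sinθ dθ via u = cosθ."""
    u, w = leggauss(order)
    # map from [-1, 1] to u = cosθ ∈ [0, 1]
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    theta = np.arccos(u)
    return theta, w


def displaced_core_shell_intensity(
    p: DisplacedCoreShellParams,
    q,
    order: int = DEFAULT_QUAD_ORDER,
    variant: str = "amplitude",
):
    """Orientation-averaged intensity of one displaced-core complex, cm².

    Parameters
    ----------
    p : DisplacedCoreShellParams
    q : array, 1/Å
    order : int
        Gauss–Legendre order of the θ quadrature.
    variant : {"amplitude", "exact"}
        "amplitude" squares the J0-weighted amplitude (core self-term gets
        J0²); "exact" is the exact azimuthal average of the intensity, where
        J0 appears only in the shell–core cross term. The two coincide at
        s = 0.

    Multiply by the complex number density (cm⁻³) for absolute intensity.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    theta, w = _gauss_theta(order)
    r1 = effective_radius(p.R1, p.eps1, theta)  # (order,)
    r2 = effective_radius(p.R2, p.eps2, theta)
    qq = q[:, None]
    A1 = p.k1 * sphere_amplitude(qq * r1[None, :])
    A2 = p.k2 * sphere_amplitude(qq * r2[None, :])
    bes = j0(qq * (p.s * np.sin(theta))[None, :])
    if variant == "amplitude":
        integrand = (A1 + A2 * bes) ** 2
    elif variant == "exact":
        integrand = A1**2 + A2**2 + 2.0 * A1 * A2 * bes
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return integrand @ w


def concentric_core_shell_intensity(
    p: MicelleParams, q, order: int = DEFAULT_QUAD_ORDER
):
    """Concentric core–shell ellipsoid of revolution (free micelle), cm²."""
    return displaced_core_shell_intensity(p.as_displaced(), q, order=order)


def _random_flight_integer(N: int, x: np.ndarray) -> np.ndarray:
    """S(q) = 1 + (2/N)·Σ_{k=1}^{N−1} (N−k)·x^k for integer cluster size N."""
    if N <= 1:
        return np.ones_like(x)
    S = np.ones_like(x)
    xk = np.ones_like(x)
    for k in range(1, N):
        xk = xk * x
        S += (2.0 / N) * (N - k) * xk
    return S


def random_flight_sf(p: RandomFlightParams, q):
    """Random-flight structure factor of a cluster of complexes.

    ``x = sin(q·Dmic)/(q·Dmic)`` is the phase factor of one step of length
    Dmic (centre-to-centre distance). For non-integer Nmic the structure
    factor interpolates linearly between the two bracketing integers,
    S = (1−w)·S(⌊N⌋) + w·S(⌊N⌋+1) with w = Nmic − ⌊N⌋, which makes S(q)
    continuous in Nmic and preserves S(0) = Nmic.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = np.sinc(q * p.Dmic / np.pi)  # sin(qD)/(qD), safe at q = 0
    lo = int(np.floor(p.Nmic))
    wfrac = p.Nmic - lo
    S = _random_flight_integer(lo, x)
    if wfrac > 0:
        S = (1.0 - wfrac) * S + wfrac * _random_flight_integer(lo + 1, x)
    return S


def gaussian_chain_intensity(p: GaussianChainParams, q):
    """Debye Gaussian-chain intensity I(q) = I0·2(e^{−x} − 1 + x)/x², x = q²Rg².

    Series expansion below x = 1e-4 avoids cancellation; I(0) = I0.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = (q * p.Rg) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0
    xl = x[~small]
    out[~small] = 2.0 * (np.expm1(-xl) + xl) / xl**2
    return p.I0 * out
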