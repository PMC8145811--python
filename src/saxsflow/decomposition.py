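"""Species decomposition of refolding frames.

Each refolding frame is modelled as a linear combination of basis curves:

    I(q) = a1·I_complex + a2·I_micelle + a3·I_native + a4·I_chain + a5

where I_complex, I_micelle (mixed SDS/C12E8) and I_native are measured
curves with their own counting-statistics errors, I_chain is the parametric
Gaussian-chain curve of the transiently unfolded monomer, and a5 absorbs a
flat background. Conservation of total protein mass ties the protein
scales together, ``a1 = 1 - a3 - a4``, which is substituted before
optimisation (a1 is never a free parameter).

The goodness of fit is evaluated in two steps: first the usual reduced
chi-square with the frame's errors, then a second pass in which the basis
curves' own noise is propagated by replacing the frame variance with
``sigma_j^2 = a1^2 sigma_1j^2 + a2^2 sigma_2j^2 + a3^2 sigma_3j^2`` (the
noise-free chain model contributes none). By default the replacement is
literal; ``include_measurement_sigma=True`` adds the frame variance in
quadrature instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize

from .curves import ScatteringCurve
from .models import GaussianChainParams, gaussian_chain_intensity

logger = logging.getLogger(__name__)

#: condition number above which the basis is warned collinear
COLLINEARITY_THRESHOLD = 1e6


@dataclass
class BasisSet:
    """Measured basis curves on a common q-grid plus the chain prefactor.

    ``I0_chain`` is the absolute forward scattering of the fully monomeric
    protein solution (1/cm); the Gaussian-chain basis curve is generated
    from it at whatever Rg the schedule dictates.
    """

    complex: ScatteringCurve
    micelle: ScatteringCurve
    native: ScatteringCurve
    I0_chain: float

    def __post_init__(self) -> None:
        qs = self.complex.q
        for name in ("micelle", "native"):
            c = getattr(self, name)
            if c.q.shape != qs.shape or not np.allclose(c.q, qs):
                raise ValueError("basis curves must share one q-grid")

    def resampled_to(self, q: np.ndarray) -> "BasisSet":
        """Linear interpolation onto ``q``; sigma interpolated in quadrature."""
        if q.shape == self.complex.q.shape and np.allclose(q, self.complex.q):
            return self

        def interp(c: ScatteringCurve) -> ScatteringCurve:
            I = np.interp(q, c.q, c.I)
            var = np.interp(q, c.q, c.sigma**2)
            return ScatteringCurve(q=q, I=I, sigma=np.sqrt(var), label=c.label)

        return BasisSet(
            complex=interp(self.complex),
            micelle=interp(self.micelle),
            native=interp(self.native),
            I0_chain=self.I0_chain,
        )


@dataclass
class ScaleFactors:
    """Per-frame species weights; a1 is always 1 - a3 - a4 by construction."""

    a1: float  # protein-SDS complex
    a2: float  # mixed micelle
    a3: float  # native protein
    a4: float  # Gaussian chain (unfolded monomer)
    a5: float  # flat background, 1/cm
    time_s: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.a1 - (1.0 - self.a3 - self.a4)) > 1e-12:
            raise ValueError("mass conservation violated: a1 != 1 - a3 - a4")
        for name in ("a1", "a2", "a3", "a4"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be nonnegative")


def _solve_weighted(
    X: np.ndarray, y: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Bounded weighted linear LSQ for (a2, a3, a4, a5) with a3 + a4 <= 1."""
    Xw = X / sigma[:, None]
    yw = y / sigma
    lb = np.array([0.0, 0.0, 0.0, -np.inf])
    ub = np.array([np.inf, 1.0, 1.0, np.inf])
    sol = lsq_linear(Xw, yw, bounds=(lb, ub))
    x = sol.x
    if x[1] + x[2] > 1.0 + 1e-10:
        # re-solve with the simplex constraint a3 + a4 <= 1 active
        res = minimize(
            lambda v: float(np.sum((Xw @ v - yw) ** 2)),
            x0=np.clip(x, lb, [1e6, 1.0, 1.0, 1e6]),
            jac=lambda v: 2.0 * Xw.T @ (Xw @ v - yw),
            bounds=[(0, None), (0, 1), (0, 1), (None, None)],
            constraints=[{"type": "ineq", "fun": lambda v: 1.0 - v[1] - v[2]}],
            method="SLSQP",
        )
        x = res.x
    return x


def decompose_frame(
    frame: ScatteringCurve,
    basis: BasisSet,
    Rg: float = 30.0,
    include_measurement_sigma: bool = False,
) -> tuple[ScaleFactors, float]:
    """Decompose one frame; returns the scale factors and the final χ²_red.

    Mass conservation is substituted before optimisation: with
    ``a1 = 1 - a3 - a4`` the model becomes

        I - I1 = a2·I2 + a3·(I3 - I1) + a4·(I4 - I1) + a5

    solved by bounded weighted linear least squares (a2, a3, a4 >= 0;
    a3 + a4 <= 1). Both chi-square passes are executed; the reported
    chi-square uses the basis-propagated errors of the second pass.
    """
    basis = basis.resampled_to(frame.q)
    I1, s1 = basis.complex.I, basis.complex.sigma
    I2, s2 = basis.micelle.I, basis.micelle.sigma
    I3, s3 = basis.native.I, basis.native.sigma
    I4 = gaussian_chain_intensity(GaussianChainParams(Rg=Rg, I0=basis.I0_chain), frame.q)
    X = np.column_stack([I2, I3 - I1, I4 - I1, np.ones_like(frame.q)])
    y = frame.I - I1

    cond = np.linalg.cond(X / frame.sigma[:, None])
    if cond > COLLINEARITY_THRESHOLD:
        warnings.warn(
            f"basis curves nearly collinear (condition number {cond:.2e})",
            stacklevel=2,
        )

    # step 1: frame errors only
    x = _solve_weighted(X, y, frame.sigma)
    # step 2: propagate basis noise into the weights and re-solve
    for _ in range(2):
        a2, a3, a4 = x[0], x[1], x[2]
        a1 = 1.0 - a3 - a4
        var = a1**2 * s1**2 + a2**2 * s2**2 + a3**2 * s3**2
        if include_measurement_sigma:
            var = var + frame.sigma**2
        floor = 1e-12 * float(np.max(frame.sigma)) ** 2
        sigma_eff = np.sqrt(np.maximum(var, floor))
        x = _solve_weighted(X, y, sigma_eff)

    a2, a3, a4, a5 = x
    a1 = 1.0 - a3 - a4
    resid = (y - X @ x) / sigma_eff
    nfree = 4
    chi2_red = float(np.sum(resid**2)) / max(len(frame) - nfree, 1)

    flags: list[str] = []
    total = np.mean(np.abs(frame.I))
    protein_part = np.mean(np.abs(a1 * I1 + a3 * I3 + a4 * I4))
    if total > 0 and protein_part < 0.01 * total:
        flags.append("no-protein-signal")
        logger.warning(
            "frame t=%s: protein contribution <1%% of intensity; "
            "mass-conservation scales are unconstrained",
            frame.time_s,
        )
    scales = ScaleFactors(
        a1=a1, a2=a2, a3=max(a3, 0.0), a4=max(a4, 0.0), a5=a5,
        time_s=frame.time_s, flags=flags,
    )
    return scales, chi2_red


@dataclass
class RgSchedule:
    """Chain Rg per frame: constant default with an early-frame override."""

    rg: float = 30.0
    early_rg: float | None = None
    early_until_s: float = 0.0

    def __call__(self, time_s: float | None) -> float:
        if (
            self.early_rg is not None
            and time_s is not None
            and time_s < self.early_until_s
        ):
            return self.early_rg
        return self.rg


def decompose_series(
    series: list[ScatteringCurve],
    basis: BasisSet,
    rg_schedule: RgSchedule | float = 30.0,
    include_measurement_sigma: bool = False,
) -> pd.DataFrame:
    """Decompose a time-ordered refolding series frame by frame.

    Returns a DataFrame with columns time_s, a1..a5, rg, chi2_red, flags.
    """
    if isinstance(rg_schedule, (int, float)):
        rg_schedule = RgSchedule(rg=float(rg_schedule))
    rows = []
    for frame in series:
        rg = rg_schedule(frame.time_s)
        scales, chi2 = decompose_frame(
            frame, basis, Rg=rg, include_measurement_sigma=include_measurement_sigma
        )
        rows.append(
            {
                "time_s": frame.time_s,
                "a1": scales.a1,
                "a2": scales.a2,
                "a3": scales.a3,
                "a4": scales.a4,
                "a5": scales.a5,
                "rg": rg,
                "chi2_red": chi2,
                "flags": ";".join(scales.flags),
            }
        )
    return pd.DataFrame(rows)
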