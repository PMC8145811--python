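"""Multi-exponential fitting of stopped-flow kinetic traces.

Traces — spectroscopic signals or fitted SAXS parameters/fractions against
time — are described by

    y(t) = y_inf + sum_i A_i * exp(-k_i * t),      i = 1..n, n <= 3

and summarised by half-times ``t_1/2,i = ln2 / k_i``. Multi-exponential
fitting is notoriously degenerate; initialisation here uses variable
projection over a log-spaced rate grid (amplitudes and offset are linear
given the rates, so every candidate rate set costs one linear solve),
followed by a full nonlinear trust-region refinement with positive rates
enforced through a log parameterisation. The model order can be chosen
automatically with a nested F-test at the 1% level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class KineticTrace:
    """A (t, y) trace with optional weights."""

    t: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")

    def weights(self) -> np.ndarray:
        if self.sigma is None:
            return np.ones_like(self.y)
        return 1.0 / self.sigma


@dataclass
class ExponentialFit:
    """Result of an n-exponential decay fit (rates sorted descending)."""

    n: int
    amplitudes: np.ndarray
    rates: np.ndarray            # 1/s, descending
    offset: float
    chi2_red: float
    amplitude_err: np.ndarray | None = None
    rate_err: np.ndarray | None = None
    offset_err: float | None = None
    success: bool = True
    flags: list[str] = field(default_factory=list)
    correlation: np.ndarray | None = field(default=None, repr=False)

    @property
    def halftimes(self) -> np.ndarray:
        """t_1/2,i = ln2/k_i, same order as rates (fastest first)."""
        return LN2 / self.rates

    @property
    def halftime_err(self) -> np.ndarray | None:
        """Delta-method propagation: d(t1/2)/dk = -ln2/k^2."""
        if self.rate_err is None:
            return None
        return LN2 / self.rates**2 * self.rate_err

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + np.sum(
            self.amplitudes[:, None] * np.exp(-np.outer(self.rates, t)), axis=0
        )


def _linear_solve(t, y, w, rates):
    """Amplitudes + offset for fixed rates (variable projection step)."""
    X = np.column_stack([np.exp(-k * t) for k in rates] + [np.ones_like(t)])
    Xw, yw = X * w[:, None], y * w
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    return coef, float(np.sum(resid**2))


def _grid_init(t, y, w, n, grid_size=16, top_k=4):
    """Best rate n-tuples from a log-spaced grid spanning the time window.

    Returns the ``top_k`` lowest-cost candidate tuples; refining several
    guards against the collapsed-rates local minima of this problem.
    """
    tmin = max(t[t > 0].min() if np.any(t > 0) else t[1], 1e-9)
    kgrid = np.geomspace(0.05 / t.max(), 3.0 / tmin, grid_size)
    scored = []
    for rates in combinations(kgrid, n):
        _, cost = _linear_solve(t, y, w, rates)
        scored.append((cost, rates))
    scored.sort(key=lambda item: item[0])
    return [np.array(rates) for _, rates in scored[:top_k]]


def _fit_fixed_order(trace: KineticTrace, n: int) -> ExponentialFit:
    t, y, w = trace.t, trace.y, trace.weights()
    if len(t) < 2 * n + 2:
        raise ValueError(f"need at least {2 * n + 2} points for n = {n}")
    if np.ptp(y) < 1e-14 * max(1.0, abs(np.mean(y))) or n == 0:
        # constant trace: offset-only degenerate fit
        resid = (y - np.mean(y)) * w
        return ExponentialFit(
            n=0,
            amplitudes=np.empty(0),
            rates=np.empty(0),
            offset=float(np.mean(y)),
            chi2_red=float(np.sum(resid**2)) / max(len(y) - 1, 1),
            flags=["constant-trace"],
        )
    def residual(theta):
        rates = np.exp(theta[:n])
        amps = theta[n : 2 * n]
        off = theta[2 * n]
        model = off + np.sum(amps[:, None] * np.exp(-np.outer(rates, t)), axis=0)
        return (y - model) * w

    res = None
    for k0 in _grid_init(t, y, w, n):
        amps0, _ = _linear_solve(t, y, w, k0)
        theta0 = np.concatenate([np.log(k0), amps0[:n], [amps0[n]]])
        trial = least_squares(residual, theta0, method="trf", xtol=1e-12, ftol=1e-12)
        if res is None or trial.cost < res.cost:
            res = trial
    rates = np.exp(res.x[:n])
    amps = res.x[n : 2 * n]
    offset = float(res.x[2 * n])
    order = np.argsort(rates)[::-1]
    rates, amps = rates[order], amps[order]

    ndata, npar = len(y), 2 * n + 1
    cost = float(np.sum(res.fun**2))
    chi2_red = cost / max(ndata - npar, 1)
    flags: list[str] = []
    # covariance from the Jacobian (theta space), scaled by residual variance
    rate_err = amp_err = None
    off_err = None
    corr = None
    try:
        JTJ = res.jac.T @ res.jac
        cov = np.linalg.inv(JTJ) * (cost / max(ndata - npar, 1))
        d = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(d, d)
        # d(k)/d(log k) = k
        rate_err_u = (d[:n] * np.exp(res.x[:n]))[order]
        amp_err_u = d[n : 2 * n][order]
        rate_err, amp_err = rate_err_u, amp_err_u
        off_err = float(d[2 * n])
        off_diag = corr[:n, :n][~np.eye(n, dtype=bool)]
        if n > 1 and np.any(np.abs(off_diag) > 0.999):
            flags.append("rates-ill-conditioned")
    except np.linalg.LinAlgError:
        flags.append("singular-covariance")

    slowest_t12 = LN2 / rates.min()
    if t.max() < 3.0 * slowest_t12:
        flags.append("window-short")
        warnings.warn(
            f"time window {t.max():.3g} s < 3x slowest half-time "
            f"{slowest_t12:.3g} s; slow phase poorly constrained",
            stacklevel=3,
        )
    return ExponentialFit(
        n=n,
        amplitudes=amps,
        rates=rates,
        offset=offset,
        chi2_red=chi2_red,
        amplitude_err=amp_err,
        rate_err=rate_err,
        offset_err=off_err,
        success=res.success,
        flags=flags,
        correlation=corr,
    )


def fit_exponentials(trace: KineticTrace, n: int | str = "auto") -> ExponentialFit:
    """Fit a 1–3 component exponential decay; ``n="auto"`` picks the order.

    Automatic order selection compares nested fits with an F-test at
    alpha = 0.01: the higher order is kept only when the drop in residual
    sum of squares is significant.
    """
    if n != "auto":
        return _fit_fixed_order(trace, int(n))
    alpha = 0.01
    best = _fit_fixed_order(trace, 1)
    if best.n == 0:
        return best
    ndata = len(trace.t)
    for order in (2, 3):
        if ndata < 2 * order + 2:
            break
        candidate = _fit_fixed_order(trace, order)
        p_small = 2 * best.n + 1
        p_big = 2 * order + 1
        ss_small = best.chi2_red * (ndata - p_small)
        ss_big = candidate.chi2_red * (ndata - p_big)
        if ss_big <= 0:
            best = candidate
            continue
        F = ((ss_small - ss_big) / (p_big - p_small)) / (ss_big / (ndata - p_big))
        pval = float(f_dist.sf(F, p_big - p_small, ndata - p_big))
        if pval < alpha:
            best = candidate
        else:
            break
    return best


def halftime_table(
    fits: dict[str, ExponentialFit] | list[ExponentialFit],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Half-time summary table (technique/condition rows, t1/2 columns).

    Components are reported fastest first; cells are NaN where a fit has
    fewer components, mirroring how mixed-order results are tabulated.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        labels = labels or [f"fit{i}" for i in range(len(fits))]
        items = list(zip(labels, fits))
    rows = []
    for label, fit in items:
        row: dict[str, float | str] = {"label": label, "n": fit.n}
        t12 = fit.halftimes
        err = fit.halftime_err
        for i in range(3):
            row[f"t12_{i + 1}_s"] = t12[i] if i < fit.n else np.nan
            row[f"t12_{i + 1}_err_s"] = (
                err[i] if err is not None and i < fit.n else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
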