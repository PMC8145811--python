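"""Weighted nonlinear least-squares fitting of scattering frames.

Thin layer over lmfit's trust-region least squares adding the pieces the
stopped-flow protocol needs: parameter locking, seeded Latin-hypercube
multi-starts (the oscillatory form factors have local minima), the
geometry-safe reparameterisation of the core offset, and warm-started
frame-series fits.

The core offset constraint ``s <= R1 - R2 = Dhead`` is enforced by fitting
the dimensionless ``u_s in [0, 1]`` with ``s = u_s * Dhead``, which keeps
the optimizer in a box no matter how the geometry moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import qmc

from .composition import ContrastSet, SolutionComposition, complex_intensity_absolute
from .curves import ScatteringCurve

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Best-fit parameters of one frame with uncertainties and diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float | None]
    chi2_red: float
    ndata: int
    nfree: int
    success: bool
    message: str = ""
    seed: int | None = None
    lmfit_result: object | None = field(default=None, repr=False)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _chi2(residuals: np.ndarray) -> float:
    return float(np.sum(residuals**2))


def _sample_starts(
    params: lmfit.Parameters, n_starts: int, seed: int | None
) -> list[dict[str, float]]:
    """First start = supplied values; the rest Latin-hypercube over bounds."""
    starts: list[dict[str, float]] = [
        {n: p.value for n, p in params.items() if p.vary}
    ]
    free = [n for n, p in params.items() if p.vary]
    if n_starts <= 1 or not free:
        return starts
    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    unit = sampler.random(n_starts - 1)
    for row in unit:
        start = {}
        for u, name in zip(row, free):
            p = params[name]
            lo = p.min if np.isfinite(p.min) else p.value / 3.0
            hi = p.max if np.isfinite(p.max) else p.value * 3.0
            start[name] = lo + u * (hi - lo)
        starts.append(start)
    return starts


def fit_curve(
    evaluator,
    data: ScatteringCurve,
    params: lmfit.Parameters,
    n_starts: int = 8,
    seed: int | None = None,
) -> FitResult:
    """Fit ``evaluator(params_dict, q) -> I`` to one frame.

    Weighted by the frame's sigma; goodness of fit is the reduced
    chi-square ``sum(((I - I_fit)/sigma)^2) / (N - p)``. Locked parameters
    (``vary=False``) never move. Multi-start (Latin hypercube over the free
    parameters' boxes, seeded) guards against local minima; the best start,
    including the supplied initial point, wins, so the returned chi-square
    never exceeds the starting one.

    Non-convergence is reported in ``success``/``message``, not raised.
    """
    nfree = sum(p.vary for p in params.values())
    if len(data) < nfree + 2:
        raise ValueError("need at least p + 2 data points")

    def residual(pars: lmfit.Parameters):
        vals = {n: p.value for n, p in pars.items()}
        return (data.I - evaluator(vals, data.q)) / data.sigma

    start_cost = _chi2(residual(params))
    if nfree == 0:
        # all locked: report chi-square of the supplied model, no optimization
        return FitResult(
            params={n: p.value for n, p in params.items()},
            stderr={},
            chi2_red=start_cost / max(len(data) - 1, 1),
            ndata=len(data),
            nfree=0,
            success=True,
            message="all parameters locked; no optimization performed",
            seed=seed,
        )

    best = None
    best_cost = np.inf
    any_success = False
    for start in _sample_starts(params, n_starts, seed):
        trial = params.copy()
        for name, value in start.items():
            trial[name].set(value=float(np.clip(value, trial[name].min, trial[name].max)))
        try:
            res = lmfit.minimize(
                residual, trial, method="least_squares", xtol=1e-10, ftol=1e-8
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            logger.debug("start failed: %s", exc)
            continue
        cost = _chi2(res.residual)
        any_success = any_success or res.success
        if cost < best_cost:
            best_cost = cost
            best = res
    if best is None or best_cost > start_cost + 1e-9:
        # fall back to the supplied point; never return worse than the start
        return FitResult(
            params={n: p.value for n, p in params.items()},
            stderr={n: None for n, p in params.items() if p.vary},
            chi2_red=start_cost / max(len(data) - nfree, 1),
            ndata=len(data),
            nfree=nfree,
            success=False,
            message="no start improved on the initial parameters",
            seed=seed,
        )
    stderr = {
        n: (best.params[n].stderr if best.params[n].vary else None)
        for n in best.params
        if best.params[n].vary
    }
    return FitResult(
        params={n: p.value for n, p in best.params.items()},
        stderr=stderr,
        chi2_red=best_cost / max(len(data) - nfree, 1),
        ndata=len(data),
        nfree=nfree,
        success=bool(any_success),
        message=str(getattr(best, "message", "")),
        seed=seed,
        lmfit_result=best,
    )


# ---------------------------------------------------------------------------
# displaced-core complex model: parameter builder and evaluator


def make_complex_params(
    Rcore: float,
    eps: float,
    Dhead: float,
    s: float,
    Npro: float,
    Nmic: float = 1.0,
    lock: tuple[str, ...] = ("eps", "Nmic"),
) -> lmfit.Parameters:
    """lmfit parameter set for the displaced-core complex fit.

    The offset enters as ``u_s = s/Dhead in [0, 1]`` so the constraint
    ``s <= R1 - R2`` holds throughout. ``lock`` names parameters frozen at
    their initial values (the series protocols lock eps and usually Dhead).
    """
    p = lmfit.Parameters()
    p.add("Rcore", value=Rcore, min=3.0, max=40.0)
    p.add("eps", value=eps, min=0.3, max=6.0)
    p.add("Dhead", value=Dhead, min=3.0, max=30.0)
    p.add("u_s", value=np.clip(s / max(Dhead, 1e-9), 0.0, 1.0), min=0.0, max=1.0)
    p.add("Npro", value=Npro, min=0.0, max=6.0)
    p.add("Nmic", value=Nmic, min=1.0, max=30.0)
    for name in lock:
        key = "u_s" if name == "s" else name
        p[key].set(vary=False)
    return p


def complex_evaluator(
    comp: SolutionComposition,
    cs: ContrastSet,
    Dmic: float = 50.0,
    variant: str = "amplitude",
):
    """Absolute-scale evaluator for :func:`fit_curve`.

    Composition totals stay fixed (modelling on absolute scale): each
    evaluation recomputes aggregation number, contrasts and number density
    from the trial geometry.
    """

    def evaluate(vals: dict[str, float], q):
        c = SolutionComposition(
            c_protein=comp.c_protein,
            C_SDS_total=comp.C_SDS_total,
            C_SDS_free=comp.C_SDS_free,
            C_C12E8=comp.C_C12E8,
            Npro=vals["Npro"],
            Nmic=vals.get("Nmic", 1.0),
        )
        s = vals["u_s"] * vals["Dhead"]
        try:
            return complex_intensity_absolute(
                q,
                Rcore=vals["Rcore"],
                eps=vals["eps"],
                Dhead=vals["Dhead"],
                s=s,
                comp=c,
                cs=cs,
                Dmic=Dmic,
                variant=variant,
            )
        except ValueError:
            # infeasible geometry/composition (overfilled shell): steer the
            # optimizer away with a large, finite penalty
            return np.full_like(np.atleast_1d(np.asarray(q, float)), 1e6)

    return evaluate


def fit_unfolding_series(
    series: list[ScatteringCurve],
    params: lmfit.Parameters,
    evaluator,
    n_starts: int = 8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit every frame of a time-ordered series, warm-starting each frame.

    Frame 0 gets the full multi-start budget; frame i+1 starts from frame
    i's solution with a single start (the structures evolve smoothly, so
    the previous solution is an excellent start and identical frames are a
    fixed point). A non-converged frame is flagged in the output row, never
    aborts the series.

    Returns a DataFrame with time, parameter values, stderr columns
    (``<name>_err``), reduced chi-square, ``s`` in Å, and a success flag.
    """
    rows = []
    current = params.copy()
    for i, frame in enumerate(series):
        result = fit_curve(
            evaluator,
            frame,
            current,
            n_starts=n_starts if i == 0 else 1,
            seed=seed,
        )
        row: dict[str, float] = {"time_s": frame.time_s, "chi2_red": result.chi2_red}
        for name, value in result.params.items():
            row[name] = value
            if name in result.stderr:
                err = result.stderr[name]
                row[f"{name}_err"] = np.nan if err is None else err
        row["s"] = result.params["u_s"] * result.params["Dhead"]
        row["success"] = result.success
        rows.append(row)
        for name, value in result.params.items():
            current[name].set(value=value)
    return pd.DataFrame(rows)
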