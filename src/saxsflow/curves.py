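"""Scattering-curve containers and ASCII I/O.

Unit conventions used throughout the package are fixed here at the boundary:
the scattering-vector modulus ``q`` is in reciprocal angstrom, absolute
intensities ``I`` and their standard errors ``sigma`` are in 1/cm, and frame
time stamps are seconds after mixing (mid-exposure time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative error assigned when a curve file carries no sigma column
DEFAULT_RELATIVE_SIGMA = 0.02


@dataclass
class ScatteringCurve:
    """One reduced SAXS frame on absolute scale.

    Parameters
    ----------
    q : array
        Scattering-vector modulus, 1/Å, strictly increasing, all positive.
    I : array
        Intensity, 1/cm.
    sigma : array
        Standard error of ``I``, 1/cm, positive wherever ``I`` is finite.
    time_s : float, optional
        Mid-exposure time of the frame since mixing, seconds.
    label : str
        Free-text description.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    time_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.size == 0:
            raise ValueError("empty curve")
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I, sigma must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q not increasing")
        finite = np.isfinite(self.I)
        if np.any(self.sigma[finite] <= 0):
            raise ValueError("sigma must be > 0 where I is finite")

    def __len__(self) -> int:
        return self.q.size

    def with_time(self, time_s: float) -> "ScatteringCurve":
        return replace(self, time_s=time_s)


@dataclass
class SeriesManifest:
    """Ordered stopped-flow frame series: (file reference, time) pairs."""

    entries: list[tuple[str, float]] = field(default_factory=list)
    deadtime_s: float = 0.0

    def __post_init__(self) -> None:
        times = [t for _, t in self.entries]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("manifest times must be strictly increasing")
        if times and times[0] < self.deadtime_s:
            raise ValueError("first frame precedes the instrument deadtime")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, t in self.entries], dtype=float)


def read_curve(path: str | Path) -> ScatteringCurve:
    """Read a whitespace-separated ASCII curve file (``q I [sigma]``).

    Comment lines start with ``#``; a ``# time_s=`` / ``# label=`` header is
    honoured. Rows with non-numeric fields are skipped (count logged). A
    missing sigma column is replaced by ``DEFAULT_RELATIVE_SIGMA * I`` with a
    loud warning, since downstream chi-square weighting needs errors.
    """
    path = Path(path)
    time_s: float | None = None
    label = ""
    rows: list[list[float]] = []
    skipped = 0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("time_s="):
                    time_s = float(body.split("=", 1)[1])
                elif body.startswith("label="):
                    label = body.split("=", 1)[1]
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                skipped += 1
                continue
            if len(vals) < 2:
                skipped += 1
                continue
            rows.append(vals)
    if skipped:
        logger.warning("%s: skipped %d non-numeric rows", path.name, skipped)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q, I = arr[:, 0], arr[:, 1]
    if ncol >= 3:
        sigma = arr[:, 2]
    else:
        sigma = DEFAULT_RELATIVE_SIGMA * np.abs(I)
        logger.warning(
            "%s: no sigma column; defaulting to %.0f%% of I",
            path.name,
            100 * DEFAULT_RELATIVE_SIGMA,
        )
    return ScatteringCurve(q=q, I=I, sigma=sigma, time_s=time_s, label=label)


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3-column ASCII; metadata goes in ``#`` headers.

    Values are written with 17 significant digits so a read/write round trip
    is the identity well past 12 significant digits.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# saxsflow scattering curve: q [1/A]  I [1/cm]  sigma [1/cm]\n")
        if curve.time_s is not None:
            fh.write(f"# time_s={curve.time_s!r}\n")
        if curve.label:
            fh.write(f"# label={curve.label}\n")
        for qj, Ij, sj in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{qj:.16e} {Ij:.16e} {sj:.16e}\n")


def write_series(
    curves: Sequence[ScatteringCurve],
    directory: str | Path,
    manifest_name: str = "manifest.csv",
    deadtime_s: float = 0.0,
    prefix: str = "frame",
) -> Path:
    """Write a frame series plus its CSV manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, c in enumerate(curves):
        name = f"{prefix}_{i:04d}.dat"
        write_curve(c, directory / name)
        entries.append((name, c.time_s if c.time_s is not None else float(i)))
    manifest = SeriesManifest(entries=entries, deadtime_s=deadtime_s)
    mpath = directory / manifest_name
    with mpath.open("w") as fh:
        fh.write(f"# deadtime_s={deadtime_s!r}\n")
        fh.write("file,time_s\n")
        for name, t in manifest.entries:
            fh.write(f"{name},{t!r}\n")  # repr keeps full float precision
    return mpath


def read_series(manifest: str | Path) -> list[ScatteringCurve]:
    """Read a frame series from a CSV manifest (columns ``file,time_s``)."""
    mpath = Path(manifest)
    deadtime = 0.0
    with mpath.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            body = first.lstrip("#").strip()
            if body.startswith("deadtime_s="):
                deadtime = float(body.split("=", 1)[1])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    if not {"file", "time_s"} <= set(df.columns):
        raise ValueError(f"{mpath}: manifest needs 'file' and 'time_s' columns")
    df = df.sort_values("time_s")
    curves = []
    for _, row in df.iterrows():
        fpath = mpath.parent / str(row["file"])
        if not fpath.exists():
            raise FileNotFoundError(f"manifest frame file missing: {fpath}")
        c = read_curve(fpath)
        curves.append(c.with_time(float(row["time_s"])))
    # validates ordering / deadtime consistency
    SeriesManifest(
        entries=[(str(r["file"]), float(r["time_s"])) for _, r in df.iterrows()],
        deadtime_s=deadtime,
    )
    logger.info(
        "read %d frames spanning t = %.4g .. %.4g s",
        len(curves),
        curves[0].time_s,
        curves[-1].time_s,
    )
    return curves
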