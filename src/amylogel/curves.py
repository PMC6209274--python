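"""One-dimensional SAXS curve container and text-format I/O.

The unit of exchange throughout the package is the :class:`ScatteringCurve`:
a strictly increasing grid of scattering-vector magnitudes ``q`` (nm^-1),
intensities ``I(q)`` in arbitrary units, and optional per-point
uncertainties.  Curves are stored on disk as whitespace-separated text with
``#``-prefixed header lines (``# key: value``), compatible with the output
of common SAS reduction pipelines.  Time series are a directory of such
files plus a tab-separated manifest (``series.tsv``) mapping filename to
acquisition time in minutes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import CurveParseError, DuplicateQError, GridMismatchError

__all__ = [
    "ScatteringCurve",
    "KratkyCurve",
    "read_curve",
    "write_curve",
    "q_from_angle",
    "kratky_transform",
    "subtract_solvent",
    "read_series",
    "write_series_manifest",
]

#: Number of significant digits written to disk; 17 round-trips any float64
#: value exactly.
_FLOAT_FMT = "{:.17g}"


@dataclass
class ScatteringCurve:
    """A 1D scattering curve I(q) on a strictly increasing q grid.

    Parameters
    ----------
    q:
        Scattering-vector magnitudes in nm^-1; strictly increasing, > 0.
    intensity:
        I(q) in arbitrary units; same length as ``q``.
    sigma:
        Optional 1-sigma uncertainties on the intensity (same units).
    meta:
        Free-form metadata.  Conventional keys: ``wavelength_nm``,
        ``time_min``, ``seed``.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1:
            raise ValueError("q must be one-dimensional")
        if self.q.size == 0:
            raise ValueError("curve must contain at least one point")
        if np.any(self.q <= 0):
            raise ValueError("all q values must be > 0")
        if np.any(np.diff(self.q) <= 0):
            if np.any(np.diff(np.sort(self.q)) == 0):
                raise DuplicateQError("duplicate q values in curve")
            raise ValueError("q must be strictly increasing")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity length must match q")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
            if np.any(self.sigma < 0):
                raise ValueError("sigma values must be >= 0")

    def __len__(self) -> int:
        return self.q.size

    def window(self, qmin: float, qmax: float) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax."""
        mask = (self.q >= qmin) & (self.q <= qmax)
        if not mask.any():
            raise ValueError(f"no points in window [{qmin}, {qmax}]")
        return ScatteringCurve(
            self.q[mask],
            self.intensity[mask],
            None if self.sigma is None else self.sigma[mask],
            dict(self.meta),
        )


@dataclass
class KratkyCurve:
    """Kratky representation q^2 I(q) of a scattering curve."""

    q: np.ndarray
    kratky: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.kratky = np.asarray(self.kratky, dtype=float)
        if self.kratky.shape != self.q.shape:
            raise ValueError("kratky length must match q")


def q_from_angle(wavelength: float, two_theta: float | np.ndarray) -> float | np.ndarray:
    """Convert a scattering angle 2-theta (radians) to q = (4 pi / lambda) sin(theta).

    ``wavelength`` is in nm, the result in nm^-1.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    two_theta = np.asarray(two_theta, dtype=float)
    if np.any(two_theta < 0) or np.any(two_theta >= math.pi):
        raise ValueError("two_theta must lie in [0, pi)")
    q = (4.0 * math.pi / wavelength) * np.sin(two_theta / 2.0)
    return float(q) if q.ndim == 0 else q


def kratky_transform(curve: ScatteringCurve) -> KratkyCurve:
    """Return the Kratky curve q^2 I(q) of ``curve``."""
    return KratkyCurve(curve.q.copy(), curve.q**2 * curve.intensity)


def subtract_solvent(
    sample: ScatteringCurve,
    solvent: ScatteringCurve,
    scale: float = 1.0,
    interpolate: bool = False,
    rtol: float = 1e-6,
) -> ScatteringCurve:
    """Excess scattering: sample minus ``scale`` times solvent.

    The two q grids must agree pointwise within relative tolerance ``rtol``
    unless ``interpolate`` is set, in which case the solvent curve is
    linearly interpolated onto the sample grid (solvent uncertainties are
    dropped in that case).  Uncertainties combine in quadrature when both
    curves carry them.
    """
    if interpolate:
        solv_i = np.interp(sample.q, solvent.q, solvent.intensity)
        solv_s = None
    else:
        if sample.q.shape != solvent.q.shape or not np.allclose(
            sample.q, solvent.q, rtol=rtol, atol=0.0
        ):
            raise GridMismatchError(
                "sample and solvent q grids differ; pass interpolate=True to "
                "resample the solvent curve"
            )
        solv_i = solvent.intensity
        solv_s = solvent.sigma

    intensity = sample.intensity - scale * solv_i
    sigma = None
    if sample.sigma is not None and solv_s is not None:
        sigma = np.hypot(sample.sigma, abs(scale) * solv_s)
    elif sample.sigma is not None:
        sigma = sample.sigma.copy()
    elif solv_s is not None:
        sigma = abs(scale) * solv_s

    meta = dict(sample.meta)
    meta["solvent_subtracted"] = True
    return ScatteringCurve(sample.q.copy(), intensity, sigma, meta)


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_curve(path: str | os.PathLike) -> ScatteringCurve:
    """Read a whitespace-separated curve file (q, I, optional sigma).

    Header lines start with ``#``; lines of the form ``# key: value`` are
    collected into the curve metadata.  Rows are sorted by q.  A malformed
    numeric row raises :class:`CurveParseError` naming its line; duplicate
    q values raise :class:`DuplicateQError`.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, ...]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = _parse_meta_value(value.strip())
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise CurveParseError(
                    f"{path.name}:{lineno}: expected >= 2 columns, got {len(tokens)}",
                    line=lineno,
                )
            try:
                values = tuple(float(t) for t in tokens[:3])
            except ValueError:
                raise CurveParseError(
                    f"{path.name}:{lineno}: non-numeric token in data row",
                    line=lineno,
                ) from None
            if ncols is None:
                ncols = len(values)
            rows.append(values[: ncols if ncols is not None else 3])
    if not rows:
        raise CurveParseError(f"{path.name}: no data rows found")

    data = np.array([r[:2] for r in rows], dtype=float)
    has_sigma = all(len(r) >= 3 for r in rows)
    sigma = np.array([r[2] for r in rows], dtype=float) if has_sigma else None

    order = np.argsort(data[:, 0], kind="stable")
    q = data[order, 0]
    if np.any(np.diff(q) == 0):
        raise DuplicateQError(f"{path.name}: duplicate q values")
    return ScatteringCurve(
        q, data[order, 1], None if sigma is None else sigma[order], meta
    )


def write_curve(curve: ScatteringCurve, path: str | os.PathLike) -> None:
    """Write a curve to a 2- or 3-column text file with ``# key: value`` headers."""
    path = Path(path)
    cols = [curve.q, curve.intensity]
    names = ["q_nm^-1", "intensity"]
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names.append("sigma")
    with open(path, "w") as fh:
        for key, value in curve.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: " + " ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(_FLOAT_FMT.format(v) for v in row) + "\n")


def write_series_manifest(
    entries: Iterable[tuple[str, float]], path: str | os.PathLike
) -> None:
    """Write a ``series.tsv`` manifest (columns: filename, time_min)."""
    with open(path, "w") as fh:
        fh.write("filename\ttime_min\n")
        for filename, time_min in entries:
            fh.write(f"{filename}\t{_FLOAT_FMT.format(time_min)}\n")


def read_series(manifest: str | os.PathLike) -> list[tuple[float, ScatteringCurve]]:
    """Read a time series from a ``series.tsv`` manifest.

    Returns a list of (time_min, curve) sorted by time; each curve file is
    resolved relative to the manifest's directory.
    """
    manifest = Path(manifest)
    frames: list[tuple[float, ScatteringCurve]] = []
    with open(manifest) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["filename", "time_min"]:
            raise CurveParseError(
                f"{manifest.name}: expected header 'filename\\ttime_min'", line=1
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CurveParseError(
                    f"{manifest.name}:{lineno}: expected 2 tab-separated fields",
                    line=lineno,
                )
            try:
                t = float(parts[1])
            except ValueError:
                raise CurveParseError(
                    f"{manifest.name}:{lineno}: non-numeric time", line=lineno
                ) from None
            curve = read_curve(manifest.parent / parts[0])
            curve.meta.setdefault("time_min", t)
            frames.append((t, curve))
    frames.sort(key=lambda item: item[0])
    return frames
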