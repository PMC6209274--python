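"""Synthetic time-resolved SAXS gelation series.

The generator emulates 10% amylose gelation by in situ neutralization as a
forward model: each frame's intensity is the two-component model (rod +
stretched exponential for the low-molecular-weight system, rod +
Debye-Bueche for the high-molecular-weight one) whose structural parameters
follow sigmoidal (logistic) trajectories across the gel point, plus
phenomenological crystal diffraction peaks at q = 4 and 7 nm^-1 ramping up
after gelation, times multiplicative Gaussian noise.

Default trajectories (the study conditions):

* AM_L (low molecular weight): gel time 37 min; R_c constant at 0.6 nm;
  correlation length Xi 3 -> 17 nm; stretching exponent x 0.70 -> 0.85.
* AM_H (high molecular weight): gel time 32.5 min (mid of the observed
  31-34 min range); R_c 0.6 nm; inhomogeneity length a 3 -> 10 nm.

The pre-gel "several nm" sizes are rendered as 3 nm.  The aggregate
prefactor grows with the correlation volume, I0(t) proportional to
(size(t)/size(0))^3 — for a random two-phase medium the forward-scattering
power scales with the inhomogeneity volume — which is what makes the low-q
(0.1-0.8 nm^-1) integrated intensity rise sharply at the gel point, the
signature the gel-point detector keys on.  ``transition_width`` is the
10-90% rise time of the logistic (default 3 min).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curves import ScatteringCurve, write_curve, write_series_manifest
from .models import Eq1Params, Eq2Params, model_intensity

__all__ = [
    "GelationTrajectory",
    "NoiseSpec",
    "default_trajectory",
    "simulate_series",
    "write_fixture",
    "DEFAULT_Q_GRID",
]

#: default q grid: 0.1-8 nm^-1 covers the low-q aggregation window
#: (0.1-0.8), the model-fit window (0.1-3.5) and both diffraction peaks
DEFAULT_Q_GRID = np.linspace(0.1, 8.0, 240)

#: logistic time constant tau such that the 10-90% rise time equals w
_RISE_TO_TAU = 1.0 / (2.0 * math.log(9.0))

GEL_TIME_AML = 37.0
GEL_TIME_AMH = 32.5
PRE_GEL_SIZE = 3.0  # nm, "several nm" rendered as 3


def _logistic(t: np.ndarray, lo: float, hi: float, t0: float, tau: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-(t - t0) / tau))


@dataclass
class NoiseSpec:
    """Multiplicative Gaussian noise: I -> I * (1 + eps), eps ~ N(0, relative_sd)."""

    relative_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")


@dataclass
class GelationTrajectory:
    """Time-stamped model parameters defining a synthetic gelation series.

    ``peak_spec`` lists (position nm^-1, final height arb.u., FWHM nm^-1)
    of crystal diffraction peaks; their heights ramp linearly from zero at
    ``gel_time`` to the final height at the last frame.
    """

    times: np.ndarray
    model: str  # "eq1" | "eq2"
    params_of_time: list
    gel_time: float
    transition_width: float
    peak_spec: list[tuple[float, float, float]] = field(default_factory=list)
    system: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.model not in ("eq1", "eq2"):
            raise ValueError("model must be 'eq1' or 'eq2'")
        if len(self.params_of_time) != self.times.size:
            raise ValueError("one parameter set per frame required")
        if not (self.times.min() <= self.gel_time <= self.times.max()):
            raise ValueError("gel_time must lie within the time range")

    def peak_heights(self, t: float) -> list[float]:
        t_end = float(self.times.max())
        if t_end <= self.gel_time:
            return [0.0 for _ in self.peak_spec]
        ramp = max(0.0, (t - self.gel_time) / (t_end - self.gel_time))
        return [h * ramp for _, h, _ in self.peak_spec]


def default_trajectory(
    system: str,
    times: np.ndarray | None = None,
    transition_width: float = 3.0,
) -> GelationTrajectory:
    """Default gelation trajectory for the AM_L or AM_H system.

    Frames default to 1-60 min at 1-min spacing.
    """
    if times is None:
        times = np.arange(1.0, 61.0)
    times = np.asarray(times, dtype=float)
    tau = transition_width * _RISE_TO_TAU

    if system == "AM_L":
        gel_time = GEL_TIME_AML
        xi = _logistic(times, PRE_GEL_SIZE, 17.0, gel_time, tau)
        x = _logistic(times, 0.70, 0.85, gel_time, tau)
        i0 = (xi / PRE_GEL_SIZE) ** 3  # correlation-volume scaling, I0(0)=1
        params = [
            Eq1Params(scale_rod=1.0, rc=0.6, i0_ex=float(i0[k]), xi=float(xi[k]),
                      x=float(x[k]))
            for k in range(times.size)
        ]
        model = "eq1"
    elif system == "AM_H":
        gel_time = GEL_TIME_AMH
        a = _logistic(times, PRE_GEL_SIZE, 10.0, gel_time, tau)
        i0 = (a / PRE_GEL_SIZE) ** 3
        params = [
            Eq2Params(scale_rod=1.0, rc=0.6, i0_db=float(i0[k]), a=float(a[k]))
            for k in range(times.size)
        ]
        model = "eq2"
    else:
        raise ValueError(f"unknown system {system!r}; expected 'AM_L' or 'AM_H'")

    # final peak heights are small on the scale of the diffuse scattering so
    # that the Lorentzian half of the pseudo-Voigt tail is negligible inside
    # the 0.1-3.5 nm^-1 fit window; they still stand out clearly against the
    # local (rod-term) baseline of ~0.01 at q = 4 and 7 nm^-1
    return GelationTrajectory(
        times=times,
        model=model,
        params_of_time=params,
        gel_time=gel_time,
        transition_width=transition_width,
        peak_spec=[(4.0, 0.02, 0.3), (7.0, 0.01, 0.3)],
        system=system,
    )


def _pseudo_voigt(q: np.ndarray, pos: float, height: float, fwhm: float,
                  eta: float = 0.5) -> np.ndarray:
    """Unit-height pseudo-Voigt profile scaled by ``height``."""
    hwhm = fwhm / 2.0
    lorentz = 1.0 / (1.0 + ((q - pos) / hwhm) ** 2)
    gauss = np.exp(-math.log(2.0) * ((q - pos) / hwhm) ** 2)
    return height * (eta * lorentz + (1.0 - eta) * gauss)


def frame_intensity(traj: GelationTrajectory, index: int, q: np.ndarray) -> np.ndarray:
    """Noise-free model intensity of frame ``index`` on grid ``q``."""
    t = float(traj.times[index])
    intensity = model_intensity(q, traj.params_of_time[index])
    for (pos, _, fwhm), height in zip(traj.peak_spec, traj.peak_heights(t)):
        if height > 0:
            intensity = intensity + _pseudo_voigt(q, pos, height, fwhm)
    return intensity


def simulate_series(
    traj: GelationTrajectory,
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[list[tuple[float, ScatteringCurve]], list[dict]]:
    """Simulate a tr-SAXS series from a trajectory.

    Returns (frames, truth): ``frames`` is a list of (time_min, curve);
    ``truth`` records each frame's exact generating parameters and peak
    heights.  Noisy curves carry sigma = relative_sd * |I_model| (the
    generating noise scale).  Deterministic given ``noise.seed``.
    """
    q = DEFAULT_Q_GRID.copy() if q_grid is None else np.asarray(q_grid, dtype=float)
    noise = noise or NoiseSpec(relative_sd=0.0, seed=0)
    rng = np.random.default_rng(noise.seed)

    frames: list[tuple[float, ScatteringCurve]] = []
    truth: list[dict] = []
    for k, t in enumerate(traj.times):
        clean = frame_intensity(traj, k, q)
        if noise.relative_sd > 0:
            eps = rng.normal(0.0, noise.relative_sd, size=q.size)
            intensity = clean * (1.0 + eps)
            sigma = noise.relative_sd * np.abs(clean)
        else:
            intensity = clean.copy()
            sigma = None
        meta = {
            "time_min": float(t),
            "system": traj.system,
            "model": traj.model,
            "noise_relative_sd": noise.relative_sd,
            "seed": noise.seed,
        }
        frames.append((float(t), ScatteringCurve(q.copy(), intensity, sigma, meta)))
        rec = {"time_min": float(t), **traj.params_of_time[k].to_dict()}
        for (pos, _, _), h in zip(traj.peak_spec, traj.peak_heights(float(t))):
            rec[f"peak{pos:g}_height"] = h
        truth.append(rec)
    return frames, truth


def write_fixture(
    frames: Sequence[tuple[float, ScatteringCurve]],
    out_dir: str | os.PathLike,
    truth: Sequence[dict] | None = None,
) -> Path:
    """Write a series to ``out_dir`` as frame_###.dat + series.tsv (+ truth.tsv).

    Returns the manifest path; reading it back with
    :func:`amylogel.curves.read_series` reproduces the series.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, (t, curve) in enumerate(frames):
        name = f"frame_{k:03d}.dat"
        write_curve(curve, out_dir / name)
        entries.append((name, t))
    manifest = out_dir / "series.tsv"
    write_series_manifest(entries, manifest)

    if truth:
        keys = list(truth[0].keys())
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for rec in truth:
                fh.write("\t".join(f"{rec[k]:.9g}" for k in keys) + "\n")
    return manifest
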