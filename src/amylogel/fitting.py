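"""Nonlinear least-squares fitting of the two-component gel models.

Single curves are fitted by a multi-start trust-region least-squares
procedure; time series are fitted frame by frame (optionally warm-started
from the previous frame's solution) to produce parameter trajectories, and
a gel point is located from the rate of rise of the low-q integrated
intensity.

The default objective is evaluated in Kratky space — residuals are
q^2 I_model - q^2 I_obs, weighted by 1/(q^2 sigma) when uncertainties are
present — because gel fits are judged in the Kratky representation, where
the mid-q behaviour that discriminates the aggregate terms carries the most
weight.  A linear-intensity objective is available and recorded in the
result's ``fit_space`` label.  The stretching exponent produces shallow
local minima, hence the multi-start: eight deterministic starting points
(log-spaced correlation lengths crossed with two exponent values) plus the
caller's initial guess, each refined by scipy's trust-region reflective
solver; the lowest-residual solution wins, ties broken by first encounter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .curves import ScatteringCurve
from .errors import DegenerateInputError, NoGelPointError
from .models import Eq1Params, Eq2Params, model_intensity

__all__ = [
    "FitResult",
    "SeriesFitResult",
    "DEFAULT_BOUNDS_EQ1",
    "DEFAULT_BOUNDS_EQ2",
    "DEFAULT_Q_WINDOW",
    "fit_eq1",
    "fit_eq2",
    "fit_series",
    "detect_gel_point",
]

#: default fit window (nm^-1): excludes the crystal diffraction peaks at
#: q = 4 and 7 nm^-1, which the two-component models do not describe
DEFAULT_Q_WINDOW = (0.1, 3.5)

#: bounds bracket all reported parameter values by about an order of
#: magnitude; x's upper bound 2 is the Gaussian (Guinier-type) limit and its
#: lower bound keeps the stretched exponent well-conditioned
DEFAULT_BOUNDS_EQ1 = {
    "scale_rod": (0.0, np.inf),
    "rc": (0.1, 2.0),
    "i0_ex": (0.0, np.inf),
    "xi": (0.1, 100.0),
    "x": (0.2, 2.0),
    "background": (0.0, np.inf),
}
DEFAULT_BOUNDS_EQ2 = {
    "scale_rod": (0.0, np.inf),
    "rc": (0.1, 2.0),
    "i0_db": (0.0, np.inf),
    "a": (0.1, 100.0),
    "background": (0.0, np.inf),
}

_LS_OPTS = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000)


@dataclass
class FitResult:
    """Outcome of fitting one curve.

    ``stderr`` maps parameter name to its Jacobian-based standard error
    (NaN when the covariance is singular or the parameter was fixed);
    ``residual_norm`` is the weighted sum of squared residuals.
    """

    params: Eq1Params | Eq2Params
    stderr: dict[str, float]
    residual_norm: float
    n_points: int
    converged: bool
    fit_space: str
    model: str
    n_starts: int = 1

    @property
    def reduced_chi2(self) -> float:
        dof = self.n_points - sum(1 for v in self.stderr.values() if not math.isnan(v))
        return self.residual_norm / dof if dof > 0 else math.nan


@dataclass
class SeriesFitResult:
    """Per-frame fit results over a time series."""

    times: np.ndarray
    results: list[FitResult | None]
    errors: dict[int, str] = field(default_factory=dict)
    gel_time_estimate: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.results) != self.times.size:
            raise ValueError("one result per frame required")

    def parameter_trajectory(self, name: str) -> np.ndarray:
        """Fitted values of one parameter vs. time (NaN for failed frames)."""
        out = np.full(self.times.size, np.nan)
        for i, res in enumerate(self.results):
            if res is not None:
                out[i] = getattr(res.params, name)
        return out


def _normalize_fixed(fixed, init) -> dict[str, float]:
    """Accept a mapping name -> value or an iterable of names (fixed at the
    init's value); return a name -> value dict."""
    if fixed is None:
        return {}
    if isinstance(fixed, Mapping):
        return {k: float(v) for k, v in fixed.items()}
    return {name: float(getattr(init, name)) for name in fixed}


def _prepare_window(curve: ScatteringCurve, q_window, min_points: int = 8):
    sub = curve.window(*q_window)
    if len(sub) < min_points:
        raise ValueError(
            f"need >= {min_points} points in q window {q_window}, got {len(sub)}"
        )
    if np.all(sub.intensity <= 0):
        raise DegenerateInputError("no positive intensities in fit window")
    return sub


def _residual_factory(sub: ScatteringCurve, space: str):
    q = sub.q
    if space == "kratky":
        target = q**2 * sub.intensity
        weight = None
        if sub.sigma is not None and np.all(sub.sigma > 0):
            weight = 1.0 / (q**2 * sub.sigma)

        def residual(model_i):
            r = q**2 * model_i - target
            return r * weight if weight is not None else r

    elif space == "linear":
        target = sub.intensity
        weight = None
        if sub.sigma is not None and np.all(sub.sigma > 0):
            weight = 1.0 / sub.sigma

        def residual(model_i):
            r = model_i - target
            return r * weight if weight is not None else r

    else:
        raise ValueError("fit space must be 'kratky' or 'linear'")
    return residual


def _default_starts(model: str, q: np.ndarray, intensity: np.ndarray):
    """Eight deterministic multi-start parameter seeds derived from the data."""
    i_low = float(np.clip(intensity[0], 1e-12, None))
    scale0 = float(np.clip(np.median(q * intensity) * 4.0, 1e-12, None))
    lengths = np.geomspace(1.0, 40.0, 4)
    starts = []
    if model == "eq1":
        for length in lengths:
            for x0 in (0.7, 1.5):
                starts.append(
                    Eq1Params(scale_rod=scale0, rc=0.6, i0_ex=i_low, xi=length, x=x0)
                )
    else:
        for length in lengths:
            for rc0 in (0.4, 0.8):
                starts.append(
                    Eq2Params(scale_rod=scale0, rc=rc0, i0_db=i_low, a=length)
                )
    return starts


def _fit_model(
    curve: ScatteringCurve,
    model: str,
    init,
    bounds,
    fixed,
    q_window,
    space: str,
    multistart: bool,
) -> FitResult:
    param_cls = Eq1Params if model == "eq1" else Eq2Params
    default_bounds = DEFAULT_BOUNDS_EQ1 if model == "eq1" else DEFAULT_BOUNDS_EQ2
    bounds = {**default_bounds, **(bounds or {})}

    sub = _prepare_window(curve, q_window)
    residual_of = _residual_factory(sub, space)

    if init is None:
        init = _default_starts(model, sub.q, sub.intensity)[0]
    fixed_vals = _normalize_fixed(fixed, init)
    if fixed_vals:
        init = init.replace(**fixed_vals)
    for name, (lo, hi) in bounds.items():
        v = getattr(init, name)
        if name not in fixed_vals and not (lo <= v <= hi):
            raise ValueError(f"init.{name}={v} outside bounds [{lo}, {hi}]")

    free = [n for n in param_cls.names if n not in fixed_vals]
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])

    def to_params(x: np.ndarray):
        kw = dict(zip(free, x))
        kw.update(fixed_vals)
        for n in param_cls.names:
            kw.setdefault(n, getattr(init, n))
        return param_cls(**kw)

    def fun(x: np.ndarray):
        return residual_of(model_intensity(sub.q, to_params(x)))

    starts = [init]
    if multistart:
        for cand in _default_starts(model, sub.q, sub.intensity):
            starts.append(cand.replace(**fixed_vals) if fixed_vals else cand)

    best = None
    for start in starts:
        x0 = np.clip(np.array([getattr(start, n) for n in free]), lo, hi)
        # strictly interior start for the trf solver
        span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        x0 = np.clip(x0, lo + 1e-12 * span, np.where(np.isfinite(hi), hi - 1e-12 * span, x0))
        try:
            sol = least_squares(fun, x0, bounds=(lo, hi), x_scale="jac", **_LS_OPTS)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise DegenerateInputError("least-squares solver failed from every start")

    params = to_params(best.x)
    residual_norm = float(2.0 * best.cost)  # sum of squared residuals
    converged = bool(best.success) and math.isfinite(residual_norm)

    stderr = {n: math.nan for n in param_cls.names}
    n_pts = len(sub)
    dof = n_pts - len(free)
    if dof > 0 and best.jac is not None:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (residual_norm / dof)
            errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            for n, e in zip(free, errs):
                stderr[n] = float(e)
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        params=params,
        stderr=stderr,
        residual_norm=residual_norm,
        n_points=n_pts,
        converged=converged,
        fit_space=space,
        model=model,
        n_starts=len(starts),
    )


def fit_eq1(
    curve: ScatteringCurve,
    init: Eq1Params | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | Iterable[str] | None = None,
    q_window: tuple[float, float] = DEFAULT_Q_WINDOW,
    space: str = "kratky",
    multistart: bool = True,
) -> FitResult:
    """Fit the rod + stretched-exponential model to one curve.

    ``fixed`` may be a mapping name -> value (the parameter is pinned at
    that value) or an iterable of names pinned at the init's values.
    """
    return _fit_model(curve, "eq1", init, bounds, fixed, q_window, space, multistart)


def fit_eq2(
    curve: ScatteringCurve,
    init: Eq2Params | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | Iterable[str] | None = None,
    q_window: tuple[float, float] = DEFAULT_Q_WINDOW,
    space: str = "kratky",
    multistart: bool = True,
) -> FitResult:
    """Fit the rod + Debye-Bueche model to one curve (see :func:`fit_eq1`)."""
    return _fit_model(curve, "eq2", init, bounds, fixed, q_window, space, multistart)


def fit_series(
    frames: Sequence[tuple[float, ScatteringCurve]],
    model: str = "eq1",
    constraints: Sequence[tuple[float, float, Mapping[str, float]]] | None = None,
    warm_start: bool = True,
    init=None,
    bounds=None,
    q_window: tuple[float, float] = DEFAULT_Q_WINDOW,
    space: str = "kratky",
    detect_gel: bool = True,
) -> SeriesFitResult:
    """Fit every frame of a time series, in time order.

    ``constraints`` is a list of (t_start, t_end, {name: value}) rules;
    a frame whose time lies in [t_start, t_end) has those parameters fixed
    (e.g. ``[(50, inf, {"rc": 0.45})]`` reproduces the post-50-minute fixed
    cross-section radius).  With ``warm_start`` each frame's initial guess
    is the previous frame's solution (the first frame still gets the full
    multi-start).  Frames whose fit degenerates are recorded in ``errors``
    and the series continues.
    """
    if len(frames) < 2:
        raise ValueError("a series needs at least 2 frames")
    frames = sorted(frames, key=lambda item: item[0])
    times = np.array([t for t, _ in frames], dtype=float)

    fit_fn = fit_eq1 if model == "eq1" else fit_eq2
    results: list[FitResult | None] = []
    errors: dict[int, str] = {}
    prev_params = init
    for i, (t, curve) in enumerate(frames):
        fixed_here: dict[str, float] = {}
        for t0, t1, rule in constraints or ():
            if t0 <= t < t1:
                fixed_here.update(rule)
        use_init = prev_params if (warm_start and prev_params is not None) else init
        try:
            res = fit_fn(
                curve,
                init=use_init,
                bounds=bounds,
                fixed=fixed_here or None,
                q_window=q_window,
                space=space,
                multistart=(i == 0) or not warm_start or bool(fixed_here),
            )
            results.append(res)
            prev_params = res.params if warm_start else None
        except (DegenerateInputError, ValueError) as exc:
            results.append(None)
            errors[i] = str(exc)

    gel_time = None
    if detect_gel:
        try:
            gel_time = detect_gel_point(frames)
        except NoGelPointError:
            gel_time = None
    return SeriesFitResult(times, results, errors, gel_time)


def detect_gel_point(
    frames: Sequence[tuple[float, ScatteringCurve]],
    q_low_window: tuple[float, float] = (0.1, 0.8),
) -> float:
    """Locate the gel point as the time of maximum rate of low-q intensity rise.

    Per frame, I(q) is integrated (trapezoid) over ``q_low_window``; the
    rate of change is formed by centered finite differences, and the time of
    the maximum rate is refined by fitting a parabola through the
    neighbouring rate samples.  A flat series raises
    :class:`NoGelPointError`; a near-constant (e.g. linear-in-time) rate
    emits a flat-rate warning and returns the interior argmax.
    """
    if len(frames) < 3:
        raise ValueError("gel-point detection needs at least 3 frames")
    frames = sorted(frames, key=lambda item: item[0])
    times = np.array([t for t, _ in frames], dtype=float)
    area = np.empty(times.size)
    for i, (_, curve) in enumerate(frames):
        sub = curve.window(*q_low_window)
        area[i] = np.trapezoid(sub.intensity, sub.q)

    rate = np.gradient(area, times)  # centered differences, one-sided at ends
    interior = rate[1:-1]
    floor = 1e-9 * max(np.max(np.abs(area)), 1e-300)
    if np.max(interior) <= floor:
        raise NoGelPointError("low-q intensity trace is flat; no gel point")

    spread = np.max(interior) - np.min(interior)
    if spread <= 0.05 * np.max(np.abs(interior)):
        warnings.warn(
            "low-q intensity rate is nearly constant; gel time is ill-defined",
            RuntimeWarning,
            stacklevel=2,
        )
    k = 1 + int(np.argmax(interior))
    # parabolic refinement on the (time, rate) triple around the argmax
    t0, t1, t2 = times[k - 1 : k + 2]
    r0, r1, r2 = rate[k - 1 : k + 2]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    if denom != 0:
        a = (t2 * (r1 - r0) + t1 * (r0 - r2) + t0 * (r2 - r1)) / denom
        b = (t2**2 * (r0 - r1) + t1**2 * (r2 - r0) + t0**2 * (r1 - r2)) / denom
        if a < 0:
            vertex = -b / (2.0 * a)
            if t0 <= vertex <= t2:
                return float(vertex)
    return float(times[k])
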