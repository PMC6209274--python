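"""Closed-form scattering models for gelling amylose solutions.

The gel is treated as a two-component system: dissolved rod-like chains
plus an aggregated (solid-like) phase.  The dissolved chains contribute the
infinitely-thin-long-cylinder cross-section term

    I_rod(q) = scale_rod * (1/q) * [J1(q R_c) / (q R_c)]^2,

with R_c the cross-sectional radius and J1 the first-order Bessel function.
The aggregate contributes either a stretched exponential,

    I_ex(q) = I(0)_ex * exp[-(q Xi)^x],        0 < x <= 2,

with Xi the mean size of the solid-like non-uniformity (x = 2 recovers a
Gaussian / Guinier-type region), or the Debye-Bueche form for a random
two-phase medium,

    I_DB(q) = I(0)_DB / (1 + a^2 q^2)^2,

with a the inhomogeneity length.  The low-molecular-weight system is fitted
with rod + stretched exponential, the high-molecular-weight system with
rod + Debye-Bueche.  Intensities are in arbitrary units, so each component
carries a free prefactor; an optional flat background (default 0) is
available for real excess-scattering curves.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np
from scipy.special import j1

__all__ = [
    "Eq1Params",
    "Eq2Params",
    "rod_term",
    "stretched_exp_term",
    "debye_bueche_term",
    "lorentzian_term",
    "eq1_intensity",
    "eq2_intensity",
]


@dataclass(frozen=True)
class Eq1Params:
    """Rod + stretched-exponential parameter set.

    Units: ``scale_rod`` arb.u.*nm, ``rc`` nm, ``i0_ex`` arb.u., ``xi`` nm,
    ``x`` dimensionless, ``background`` arb.u.
    """

    scale_rod: float
    rc: float
    i0_ex: float
    xi: float
    x: float
    background: float = 0.0

    #: parameter names in canonical order (used by fitting and reports)
    names = ("scale_rod", "rc", "i0_ex", "xi", "x", "background")

    def __post_init__(self) -> None:
        if self.scale_rod < 0 or self.i0_ex < 0:
            raise ValueError("prefactors must be >= 0")
        if self.rc <= 0:
            raise ValueError("rc must be > 0")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")
        if not (0 < self.x <= 2):
            raise ValueError("x must lie in (0, 2]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Eq1Params":
        return cls(**{k: float(d[k]) for k in cls.names if k in d})

    def replace(self, **kw) -> "Eq1Params":
        return replace(self, **kw)


@dataclass(frozen=True)
class Eq2Params:
    """Rod + Debye-Bueche parameter set.

    Units: ``scale_rod`` arb.u.*nm, ``rc`` nm, ``i0_db`` arb.u., ``a`` nm,
    ``background`` arb.u.
    """

    scale_rod: float
    rc: float
    i0_db: float
    a: float
    background: float = 0.0

    names = ("scale_rod", "rc", "i0_db", "a", "background")

    def __post_init__(self) -> None:
        if self.scale_rod < 0 or self.i0_db < 0:
            raise ValueError("prefactors must be >= 0")
        if self.rc <= 0:
            raise ValueError("rc must be > 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Eq2Params":
        return cls(**{k: float(d[k]) for k in cls.names if k in d})

    def replace(self, **kw) -> "Eq2Params":
        return replace(self, **kw)


def _check_positive_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("rod term requires q > 0 (diverges at q = 0)")
    return q


def rod_term(q, scale_rod: float, rc: float):
    """Cross-section scattering of infinitely thin long rods.

    scale_rod * (1/q) [J1(q rc)/(q rc)]^2.  Diverges at q = 0, so q must be
    strictly positive.
    """
    if rc <= 0:
        raise ValueError("rc must be > 0")
    q = _check_positive_q(q)
    u = q * rc
    return scale_rod * (1.0 / q) * (j1(u) / u) ** 2


def stretched_exp_term(q, i0_ex: float, xi: float, x: float):
    """Aggregate term i0_ex * exp[-(q xi)^x] for 0 < x <= 2."""
    if xi <= 0:
        raise ValueError("xi must be > 0")
    if not (0 < x <= 2):
        raise ValueError("x must lie in (0, 2]")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    return i0_ex * np.exp(-((q * xi) ** x))


def debye_bueche_term(q, i0_db: float, a: float):
    """Debye-Bueche random two-phase medium: i0_db / (1 + a^2 q^2)^2."""
    if a <= 0:
        raise ValueError("a must be > 0")
    q = np.asarray(q, dtype=float)
    return i0_db / (1.0 + a**2 * q**2) ** 2


def lorentzian_term(q, i0_l: float, corr_len: float):
    """Ornstein-Zernike (Lorentzian) chain-scattering alternative.

    i0_l / (1 + corr_len^2 q^2); provided for comparison, not used by the
    default two-component fits.
    """
    if corr_len <= 0:
        raise ValueError("corr_len must be > 0")
    q = np.asarray(q, dtype=float)
    return i0_l / (1.0 + corr_len**2 * q**2)


def eq1_intensity(q, params: Eq1Params):
    """Rod + stretched-exponential model intensity on q > 0."""
    return (
        rod_term(q, params.scale_rod, params.rc)
        + stretched_exp_term(q, params.i0_ex, params.xi, params.x)
        + params.background
    )


def eq2_intensity(q, params: Eq2Params):
    """Rod + Debye-Bueche model intensity on q > 0."""
    return (
        rod_term(q, params.scale_rod, params.rc)
        + debye_bueche_term(q, params.i0_db, params.a)
        + params.background
    )


def model_intensity(q, params):
    """Dispatch on the parameter type (Eq1Params or Eq2Params)."""
    if isinstance(params, Eq1Params):
        return eq1_intensity(q, params)
    if isinstance(params, Eq2Params):
        return eq2_intensity(q, params)
    raise TypeError(f"unsupported parameter type: {type(params)!r}")
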