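"""Catch-probability model of a single baited insect trap.

A trap–insect system is summarized by three parameters:

``sptfer0``
    Probability of eventually catching (over the converged-catch interval)
    an insect located in the immediate proximity of the trap.
``d50``
    Distance (m) at which the catch probability drops to half of
    ``sptfer0`` — the effective attractive distance of the trap system.
``rmax``
    Radius (m) of the trap's collection area; the catch probability is
    identically zero beyond it.

The catch probability at distance ``r`` is the Lorentzian-shaped curve

    spTfer(r) = sptfer0 / (1 + (r / d50)**2)   for r <= rmax,  else 0,

and the expected trap catch for a radially symmetric density ``rho(r)``
(insects per m^2) is the integral ``2*pi * int_0^rmax spTfer(r) rho(r) r dr``.
For a spatially uniform density the integral has the closed form
``rho_bar / mu`` with the conversion constant

    mu = 1 / (sptfer0 * pi * d50**2 * ln(1 + (rmax/d50)**2)),

so ``mu`` converts a trap catch directly into a density (insects per m^2
per caught insect).  All internal densities are per m^2; the per-hectare
conversion (x 10,000) happens only at the reporting boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy import integrate

__all__ = [
    "TrapSystemParams",
    "ConstantDensity",
    "RadialDensityProfile",
    "sp_t_fer",
    "ln_sp_t_fer",
    "compute_mu",
    "expected_catch",
]

#: absolute and relative quadrature tolerance for the expected-catch integral
QUAD_TOL = 1e-9

#: a radially symmetric density profile: r (m) -> insects per m^2
RadialDensityProfile = Callable[[Union[float, np.ndarray]], Union[float, np.ndarray]]


@dataclass(frozen=True)
class TrapSystemParams:
    """Fitted parameters of one trap–insect system.

    Parameters
    ----------
    sptfer0 : float
        Catch probability in the immediate proximity of the trap, in (0, 1].
    d50 : float
        Half-catch distance in meters, > 0.
    rmax : float or None
        Collection-area radius in meters (> 0), or ``None`` when unknown.
        Density conversion requires a finite ``rmax``.
    d50_sem : float
        Standard error of ``d50`` in meters (0 when unknown).
    label : str
        Free-text system name, e.g. ``"L. dispar / USDA milk-carton trap"``.
    """

    sptfer0: float
    d50: float
    rmax: float | None = None
    d50_sem: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.sptfer0 <= 1.0):
            raise ValueError(
                f"sptfer0 must be in (0, 1], got {self.sptfer0!r}"
            )
        if not (self.d50 > 0.0 and math.isfinite(self.d50)):
            raise ValueError(f"d50 must be a positive finite distance, got {self.d50!r}")
        if self.d50_sem < 0.0:
            raise ValueError(f"d50_sem must be >= 0, got {self.d50_sem!r}")
        if self.rmax is not None:
            if not (self.rmax > 0.0 and math.isfinite(self.rmax)):
                raise ValueError(
                    f"rmax must be a positive finite distance or None, got {self.rmax!r}"
                )
            if self.rmax < self.d50:
                warnings.warn(
                    f"rmax ({self.rmax} m) is smaller than d50 ({self.d50} m): "
                    "the half-catch distance lies outside the collection disk",
                    UserWarning,
                    stacklevel=3,
                )

    def _require_rmax(self) -> float:
        if self.rmax is None:
            raise ValueError(
                "this operation requires a finite collection radius rmax; "
                f"params {self.label or '<unnamed>'} have rmax=None"
            )
        return self.rmax


@dataclass(frozen=True)
class ConstantDensity:
    """Spatially uniform density profile ``rho(r) = rho_bar`` (insects/m^2)."""

    rho_bar: float

    def __post_init__(self) -> None:
        if not (self.rho_bar >= 0.0 and math.isfinite(self.rho_bar)):
            raise ValueError(f"density must be finite and >= 0, got {self.rho_bar!r}")

    def __call__(self, r):
        return self.rho_bar * np.ones_like(np.asarray(r, dtype=float)) if np.ndim(r) else self.rho_bar


def sp_t_fer(r, params: TrapSystemParams):
    """Probability of catching an insect located at distance ``r`` (m).

    Vectorized over ``r``.  Exactly ``params.sptfer0`` at ``r = 0``, exactly
    half of it at ``r = d50``, and exactly 0 for ``r > rmax`` (the point
    ``r == rmax`` belongs to the non-zero branch).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("distance r must be non-negative")
    prob = params.sptfer0 / (1.0 + (arr / params.d50) ** 2)
    if params.rmax is not None:
        prob = np.where(arr <= params.rmax, prob, 0.0)
    return float(prob) if np.ndim(r) == 0 else prob


def ln_sp_t_fer(r, params: TrapSystemParams):
    """Natural log of :func:`sp_t_fer`, defined only on ``[0, rmax]``.

    This is the form fitted to log-transformed recapture proportions:
    ``ln sptfer0 - ln(1 + (r/d50)**2)``, strictly decreasing in ``r``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("distance r must be non-negative")
    if params.rmax is not None and np.any(arr > params.rmax):
        raise ValueError("ln_sp_t_fer is undefined beyond rmax (probability is 0)")
    out = math.log(params.sptfer0) - np.log1p((arr / params.d50) ** 2)
    return float(out) if np.ndim(r) == 0 else out


def compute_mu(params: TrapSystemParams) -> float:
    """Catch-to-density conversion constant ``mu`` (insects/m^2 per caught insect).

    ``mu = 1 / (sptfer0 * pi * d50**2 * ln(1 + (rmax/d50)**2))``.  Its inverse
    equals the expected catch per unit uniform density,
    ``2*pi * int_0^rmax spTfer(r) r dr``.  The dependence on ``rmax`` is weak
    (logarithmic), so a rough collection-radius estimate suffices in practice.
    """
    rmax = params._require_rmax()
    return 1.0 / (
        params.sptfer0 * math.pi * params.d50**2 * math.log1p((rmax / params.d50) ** 2)
    )


def expected_catch(profile: RadialDensityProfile, params: TrapSystemParams) -> float:
    """Expected trap catch for a radially symmetric density ``profile`` (per m^2).

    Evaluates ``2*pi * int_0^rmax spTfer(r) * profile(r) * r dr`` by adaptive
    quadrature (tolerance ``1e-9``).  For ``ConstantDensity(rho)`` this equals
    ``rho / compute_mu(params)`` up to quadrature error.
    """
    rmax = params._require_rmax()

    def integrand(r: float) -> float:
        return sp_t_fer(r, params) * float(profile(r)) * r

    value, _ = integrate.quad(
        integrand, 0.0, rmax, epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200
    )
    result = 2.0 * math.pi * value
    if not math.isfinite(result):
        raise ArithmeticError("expected catch is non-finite; check the density profile")
    return result
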