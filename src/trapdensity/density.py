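"""Most probable absolute population density and exact bounds from one catch.

Given a converged trap catch ``M`` and the system constant ``mu`` (see
:mod:`trapdensity.model`), the most probable average density over the
collection area is simply ``mu * M``, and an exact two-sided confidence
interval follows from the chi-squared (Garwood) form of the Poisson-count
interval:

    mu/2 * chi2_ppf((1-p)/2, 2M)  <=  rho_bar  <=  mu/2 * chi2_ppf(1-(1-p)/2, 2M+2)

with the 0-degrees-of-freedom quantile defined as 0, so a zero catch gives a
zero lower bound but a strictly positive upper bound — the detection
threshold an empty trap still implies.  The interval is exact and
conservative: its coverage is at least ``p`` for every true density.

``M`` must be an integer count (the degrees of freedom are ``2M`` and
``2M + 2``); fractional "average catches" are rejected rather than silently
accepted.  Densities are insects per m^2 internally; per-hectare values
(x 10,000) are carried alongside for reporting.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2

from .model import TrapSystemParams, compute_mu

__all__ = [
    "DensityEstimate",
    "most_probable_density",
    "density_bounds",
    "estimate_density",
    "bounds_table",
]

PER_HA = 10_000.0  # m^2 per hectare


def _check_catch(m) -> int:
    if isinstance(m, bool) or not isinstance(m, numbers.Integral):
        raise ValueError(f"trap catch M must be an integer count, got {m!r}")
    m = int(m)
    if m < 0:
        raise ValueError(f"trap catch M must be >= 0, got {m}")
    return m


def most_probable_density(m: int, mu: float) -> float:
    """Most probable average density (insects/m^2): ``mu * M``."""
    m = _check_catch(m)
    if not (mu > 0 and math.isfinite(mu)):
        raise ValueError(f"mu must be positive and finite, got {mu!r}")
    return mu * m


def density_bounds(m: int, mu: float, p: float = 0.95) -> tuple[float, float]:
    """Exact lower/upper density bounds (insects/m^2) at confidence ``p``."""
    m = _check_catch(m)
    if not (mu > 0 and math.isfinite(mu)):
        raise ValueError(f"mu must be positive and finite, got {mu!r}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"confidence p must be in (0, 1), got {p!r}")
    alpha = 1.0 - p
    lower = 0.0 if m == 0 else 0.5 * mu * chi2.ppf(alpha / 2.0, 2 * m)
    upper = 0.5 * mu * chi2.ppf(1.0 - alpha / 2.0, 2 * m + 2)
    return float(lower), float(upper)


@dataclass(frozen=True)
class DensityEstimate:
    """Catch, conversion constant, most probable density and its bounds."""

    m_caught: int
    mu: float  # insects/m^2 per caught insect
    rho_mp: float  # insects/m^2
    lower: float
    upper: float
    confidence: float
    params: TrapSystemParams | None = None

    @property
    def mu_per_ha(self) -> float:
        return self.mu * PER_HA

    @property
    def rho_mp_per_ha(self) -> float:
        return self.rho_mp * PER_HA

    @property
    def lower_per_ha(self) -> float:
        return self.lower * PER_HA

    @property
    def upper_per_ha(self) -> float:
        return self.upper * PER_HA

    def to_dict(self) -> dict:
        out = {
            "label": self.params.label if self.params else "",
            "sptfer0": self.params.sptfer0 if self.params else None,
            "d50_m": self.params.d50 if self.params else None,
            "rmax_m": self.params.rmax if self.params else None,
            "M": self.m_caught,
            "confidence": self.confidence,
            "mu_per_ha": self.mu_per_ha,
            "rho_mp_per_ha": self.rho_mp_per_ha,
            "lower_per_ha": self.lower_per_ha,
            "upper_per_ha": self.upper_per_ha,
        }
        return out


def estimate_density(
    m: int, params: TrapSystemParams, p: float = 0.95
) -> DensityEstimate:
    """Turn a trap catch into a :class:`DensityEstimate` for this system."""
    mu = compute_mu(params)
    rho_mp = most_probable_density(m, mu)
    lower, upper = density_bounds(m, mu, p)
    return DensityEstimate(
        m_caught=_check_catch(m),
        mu=mu,
        rho_mp=rho_mp,
        lower=lower,
        upper=upper,
        confidence=p,
        params=params,
    )


def bounds_table(
    params: TrapSystemParams, m_max: int, p: float = 0.95, per_ha: bool = True
) -> pd.DataFrame:
    """Density vs catch table for ``M = 0..m_max`` (the detection-curve view)."""
    m_max = _check_catch(m_max)
    rows = []
    for m in range(m_max + 1):
        est = estimate_density(m, params, p)
        if per_ha:
            rows.append(
                {
                    "M": m,
                    "lower_per_ha": est.lower_per_ha,
                    "rho_mp_per_ha": est.rho_mp_per_ha,
                    "upper_per_ha": est.upper_per_ha,
                }
            )
        else:
            rows.append(
                {"M": m, "lower": est.lower, "rho_mp": est.rho_mp, "upper": est.upper}
            )
    return pd.DataFrame(rows)
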