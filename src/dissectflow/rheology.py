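"""Power-law (Ostwald–de Waele) blood rheology.

Whole blood is shear-thinning: its apparent viscosity falls with shear
rate.  The power-law closure

    eta(gamma) = K * gamma**(n - 1)

with consistency index ``K`` (Pa·s^n) and exponent ``n`` captures this
over the physiological range; for ``n = 1`` it reduces to a Newtonian
fluid of viscosity ``K``.  The closure diverges at zero shear for
``n < 1``, so a low-shear floor clamps the viscosity (the floor applies
to the viscosity only — the wall shear stress ``tau = eta * gamma``
still vanishes at zero shear rate).

Defaults are the values used throughout this package's flow models:
``K = 0.08 Pa·s^n``, ``n = 0.55``, blood density ``1022 kg/m^3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PowerLawParams",
    "FluidProperties",
    "apparent_viscosity",
    "wall_shear_stress",
]


@dataclass(frozen=True)
class PowerLawParams:
    """Constitutive parameters of the power-law viscosity model.

    Attributes
    ----------
    consistency_index_K : float
        Consistency index ``K`` in Pa·s^n. Must be positive.
    exponent_n : float
        Flow-behaviour index ``n`` (dimensionless), ``0 < n <= 1.2``.
        ``n < 1`` is shear-thinning; ``n = 1`` is Newtonian.
    shear_rate_floor : float
        Shear rate (1/s) below which the viscosity is clamped to keep
        eta bounded for shear-thinning fluids.
    """

    consistency_index_K: float = 0.08
    exponent_n: float = 0.55
    shear_rate_floor: float = 0.01

    def __post_init__(self) -> None:
        if not (self.consistency_index_K > 0):
            raise ValueError("consistency index K must be > 0")
        if not (0 < self.exponent_n <= 1.2):
            raise ValueError("exponent n must satisfy 0 < n <= 1.2")
        if not (self.shear_rate_floor > 0):
            raise ValueError("shear_rate_floor must be > 0")


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid constants shared by all flow computations."""

    density: float = 1022.0  # kg/m^3
    rheology: PowerLawParams = field(default_factory=PowerLawParams)

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise ValueError("density must be > 0")


def _check_shear_rate(shear_rate):
    g = np.asarray(shear_rate, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite")
    if np.any(g < 0):
        raise ValueError("shear rate must be >= 0")
    return g


def apparent_viscosity(params: PowerLawParams, shear_rate):
    """Apparent viscosity eta(gamma) = K * max(gamma, floor)**(n-1) in Pa·s.

    Accepts scalars or arrays of non-negative shear rates (1/s).
    Strictly decreasing in the shear rate above the floor for ``n < 1``
    and bounded above by ``K * floor**(n-1)``.
    """
    g = _check_shear_rate(shear_rate)
    g_eff = np.maximum(g, params.shear_rate_floor)
    eta = params.consistency_index_K * g_eff ** (params.exponent_n - 1.0)
    if np.isscalar(shear_rate):
        return float(eta)
    return eta


def wall_shear_stress(params: PowerLawParams, wall_shear_rate):
    """Viscous wall stress tau = eta(gamma) * gamma in Pa.

    Equals ``K * gamma**n`` above the viscosity floor; exactly zero at
    zero shear rate (the floor clamps the viscosity, not the stress).
    Monotone non-decreasing in the shear rate.
    """
    g = _check_shear_rate(wall_shear_rate)
    tau = apparent_viscosity(params, g) * g
    if np.isscalar(wall_shear_rate):
        return float(tau)
    return tau
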