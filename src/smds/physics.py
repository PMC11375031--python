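"""Physical constants, Stokes-Einstein conversions and empirical size-mass scaling.

All quantities in this module are SI (kelvin, pascal-second, metre, m^2/s);
presentation layers convert to nm, pM, uL/h at the edges.

The central relation is the Stokes-Einstein equation for a sphere of
hydrodynamic radius ``R_H`` diffusing in a solvent of viscosity ``eta`` at
temperature ``T``::

    D = k_B * T / (6 * pi * eta * R_H)

which is exactly invertible, so a measured diffusion coefficient maps to a
calibration-free hydrodynamic radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidParameterError

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Scaling exponent of hydrodynamic radius with molecular weight for
#: compact globular proteins (R_H ~ M_W^{1/3}) and for expanded
#: intrinsically disordered chains (R_H ~ M_W^{0.6}).
SCALING_EXPONENTS = {"globular": 1.0 / 3.0, "disordered": 0.6}


@dataclass(frozen=True)
class SolventConditions:
    """Temperature and viscosity of the carrier medium.

    Defaults are room temperature (298.15 K) and the viscosity of water at
    25 C (8.9e-4 Pa s); both are overridable through configuration.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    viscosity : float
        Dynamic viscosity in pascal-seconds. Must be positive.
    """

    temperature: float = 298.15
    viscosity: float = 8.9e-4

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise InvalidParameterError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.viscosity > 0:
            raise InvalidParameterError(f"viscosity must be > 0 Pa s, got {self.viscosity}")


def diffusion_coefficient(r_h: float, cond: SolventConditions | None = None) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere.

    Parameters
    ----------
    r_h : float
        Hydrodynamic radius in metres; must be positive.
    cond : SolventConditions, optional
        Solvent temperature/viscosity; defaults to room-temperature water.

    Returns
    -------
    float
        Diffusion coefficient in m^2/s. Strictly decreasing in ``r_h``.
    """
    cond = cond or SolventConditions()
    if not r_h > 0:
        raise InvalidParameterError(f"hydrodynamic radius must be > 0 m, got {r_h}")
    return BOLTZMANN * cond.temperature / (6.0 * math.pi * cond.viscosity * r_h)


def hydrodynamic_radius(d: float, cond: SolventConditions | None = None) -> float:
    """Invert Stokes-Einstein: radius (m) from diffusion coefficient (m^2/s).

    Exact inverse of :func:`diffusion_coefficient`.
    """
    cond = cond or SolventConditions()
    if not d > 0:
        raise InvalidParameterError(f"diffusion coefficient must be > 0 m^2/s, got {d}")
    return BOLTZMANN * cond.temperature / (6.0 * math.pi * cond.viscosity * d)


@dataclass(frozen=True)
class SpeciesSize:
    """Paired hydrodynamic radius and diffusion coefficient of one species.

    The two fields are redundant by construction: ``r_h * d`` equals
    ``k_B T / (6 pi eta)`` for the conditions used to build the instance.
    Use the classmethods to construct consistently.
    """

    r_h: float  # metres
    d: float  # m^2/s

    @classmethod
    def from_radius(cls, r_h: float, cond: SolventConditions | None = None) -> "SpeciesSize":
        return cls(r_h=r_h, d=diffusion_coefficient(r_h, cond))

    @classmethod
    def from_diffusivity(cls, d: float, cond: SolventConditions | None = None) -> "SpeciesSize":
        return cls(r_h=hydrodynamic_radius(d, cond), d=d)

    @property
    def r_h_nm(self) -> float:
        return self.r_h * 1e9


def mw_from_rh(r_h: float, protein_class: str, prefactor: float) -> float:
    """Molecular weight (kDa) from hydrodynamic radius via empirical scaling.

    Globular proteins follow R_H = prefactor * M_W^{1/3}, disordered chains
    R_H = prefactor * M_W^{0.6}; inverting gives M_W = (R_H/prefactor)^{1/nu}.

    The prefactor is a caller-supplied calibration (same length unit as
    ``r_h`` per kDa^nu); it is deliberately not defaulted because the
    conversion constant depends on the calibration data set used.

    Parameters
    ----------
    r_h : float
        Hydrodynamic radius (any length unit, consistent with ``prefactor``).
    protein_class : {"globular", "disordered"}
        Which scaling law to invert.
    prefactor : float
        Calibration constant; must be positive.
    """
    if protein_class not in SCALING_EXPONENTS:
        raise InvalidParameterError(
            f"unknown protein class {protein_class!r}; expected one of {sorted(SCALING_EXPONENTS)}"
        )
    if not r_h > 0:
        raise InvalidParameterError(f"r_h must be > 0, got {r_h}")
    if not prefactor > 0:
        raise InvalidParameterError(f"prefactor must be > 0, got {prefactor}")
    nu = SCALING_EXPONENTS[protein_class]
    return (r_h / prefactor) ** (1.0 / nu)
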