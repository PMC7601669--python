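"""Conical track-etched nanopore geometry and conductance.

A single conical pore etched along an ion track in a thin polymer film has a
narrow *tip* opening of diameter ``d_t``, a wide *base* opening of diameter
``d_b``, and a length ``L`` equal to the membrane thickness.  Assuming
bulk-like ionic conductivity inside the pore, its conductance is

    G = kappa * pi * d_t * d_b / (4 * L)

with ``kappa`` the electrolyte conductivity.  The relation is routinely
inverted to estimate the tip diameter, which cannot be imaged directly, from
a measured conductance.  The base diameter is estimated from the total etch
time through a lab-calibrated linear factor (nm per unit etch time), and the
cone half-angle follows from the two diameters and the length.

All quantities are SI internally: meters, siemens, S/m.  Helpers that accept
human-readable lengths with unit suffixes live in :mod:`porepulse.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PoreGeometry",
    "conductance",
    "tip_diameter_from_conductance",
    "base_diameter_from_etch_time",
    "cone_half_angle",
    "PORE_1",
    "PORE_2",
]


@dataclass(frozen=True)
class PoreGeometry:
    """Conical pore described by tip/base diameters and length, in meters.

    Invariants: ``0 <= d_t <= d_b`` and ``L > 0``.  The half-angle is a
    derived quantity, see :func:`cone_half_angle`.
    """

    d_t: float
    d_b: float
    L: float

    def __post_init__(self) -> None:
        if self.d_t < 0:
            raise ValueError(f"tip diameter must be non-negative, got {self.d_t}")
        if self.d_b < self.d_t:
            raise ValueError(
                f"base diameter ({self.d_b}) must be >= tip diameter ({self.d_t})"
            )
        if self.L <= 0:
            raise ValueError(f"pore length must be positive, got {self.L}")

    @property
    def half_angle_deg(self) -> float:
        """Cone half-angle in degrees."""
        return cone_half_angle(self)


def conductance(kappa: float, geom: PoreGeometry) -> float:
    """Open-pore conductance (S) of a conical pore.

    Parameters
    ----------
    kappa
        Electrolyte conductivity in S/m; must be positive.
    geom
        Pore geometry in meters.
    """
    if kappa <= 0:
        raise ValueError(f"conductivity must be positive, got {kappa}")
    return kappa * math.pi * geom.d_t * geom.d_b / (4.0 * geom.L)


def tip_diameter_from_conductance(G: float, kappa: float, d_b: float, L: float) -> float:
    """Tip diameter (m) from a measured conductance.

    Exact algebraic inverse of :func:`conductance` for the tip diameter:
    ``d_t = 4 G L / (kappa * pi * d_b)``.
    """
    if G < 0:
        raise ValueError(f"conductance must be non-negative, got {G}")
    if kappa <= 0:
        raise ValueError(f"conductivity must be positive, got {kappa}")
    if d_b <= 0:
        raise ValueError(f"base diameter must be positive, got {d_b}")
    if L <= 0:
        raise ValueError(f"pore length must be positive, got {L}")
    return 4.0 * G * L / (kappa * math.pi * d_b)


def base_diameter_from_etch_time(t_etch: float, factor: float = 2.5) -> float:
    """Base diameter in nanometers from total etch time.

    The default factor 2.5 nm per unit etch time is a laboratory calibration
    obtained on multipore track membranes; it is exposed as a parameter
    because it depends on etchant and film.
    """
    if t_etch < 0:
        raise ValueError(f"etch time must be non-negative, got {t_etch}")
    if factor <= 0:
        raise ValueError(f"etch factor must be positive, got {factor}")
    return factor * t_etch


def cone_half_angle(geom: PoreGeometry) -> float:
    """Cone half-angle in degrees: ``atan((d_b - d_t) / (2 L))``.

    Defined from the radius difference over the pore length; equals zero for
    a cylindrical pore (``d_t == d_b``).
    """
    return math.degrees(math.atan((geom.d_b - geom.d_t) / (2.0 * geom.L)))


#: 13 um PET membrane pores used throughout the examples: a ~3 nm tip /
#: 200 nm base pore and a ~4 nm tip / 350 nm base pore.
PORE_1 = PoreGeometry(d_t=3e-9, d_b=200e-9, L=13e-6)
PORE_2 = PoreGeometry(d_t=4e-9, d_b=350e-9, L=13e-6)
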