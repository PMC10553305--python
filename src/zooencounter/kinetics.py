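"""Closed-form encounter-rate kinetics for plankton and passive particles.

The core quantity is the Gerritsen–Strickler (GS) encounter rate: the expected
number of targets entering the perception sphere of a cruising searcher per
unit time, when both searcher and targets move ballistically at constant
speeds with uniformly random directions,

    C_GS = (pi R^2 N / 6) * [ (x + y)^3 - |x - y|^3 ] / (x y),

with R the encounter radius (m), N the target number density (m^-3), y the
searcher speed and x the target speed (m s^-1).  The Rothschild–Osborn (RO)
variant adds a small-scale turbulent velocity w by replacing each speed v
with the effective speed sqrt(v^2 + w^2).

Microplastic particles are treated as stationary alleged prey (x = 0), which
is a singular point of the printed bracket; the analytic limit
C = pi R^2 N max(x, y) is used whenever either speed is (numerically) zero —
for x = 0 this is the familiar swept-cylinder clearance rate pi R^2 N y.

All computation is in SI units (m, s, particles m^-3).  Unit conversions
(mm -> m, particles L^-1 -> particles m^-3, s^-1 -> h^-1) belong at the I/O
boundary, not inside the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Union

import numpy as np

from .exceptions import DegenerateMotionError, ValidationError

__all__ = [
    "Swimmer",
    "ParticleField",
    "EncounterRate",
    "gs_rate",
    "effective_speed",
    "ro_rate",
    "turbulence_multiplier",
    "taxon_registry",
    "SPEED_TOL",
    "SECONDS_PER_HOUR",
    "LITERS_PER_M3",
]

#: Speeds below this (m s^-1) are treated as exactly zero and routed to the
#: analytic limit of the GS bracket; the rate is continuous across this
#: boundary to ~1e-9 relative.
SPEED_TOL = 1e-12

SECONDS_PER_HOUR = 3600.0
LITERS_PER_M3 = 1000.0

_ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class Swimmer:
    """A zooplankton taxon's encounter geometry and kinematics.

    Parameters
    ----------
    name : str
        Taxon label.
    speed : float
        Cruising speed y, m s^-1.  Must be >= 0.
    radius : float
        Encounter (perception) radius R, m.  Must be > 0.
    """

    name: str
    speed: float
    radius: float

    def __post_init__(self) -> None:
        if not self.speed >= 0:
            raise ValidationError(f"swimmer speed must be >= 0, got {self.speed}")
        if not self.radius > 0:
            raise ValidationError(f"encounter radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ParticleField:
    """The alleged prey: a density of particles moving at a common speed.

    ``density`` is N in particles m^-3 (scalar or array, so a whole bootstrap
    resample can be pushed through the rate formulas at once); ``speed`` is
    the particle speed x in m s^-1, zero for passively suspended microplastics.
    """

    density: _ArrayLike
    speed: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.density) < 0):
            raise ValidationError("particle density must be >= 0")
        if not self.speed >= 0:
            raise ValidationError(f"particle speed must be >= 0, got {self.speed}")

    @classmethod
    def from_per_liter(cls, concentration: _ArrayLike, speed: float = 0.0) -> "ParticleField":
        """Build a field from a concentration in particles L^-1 (x 1000 -> m^-3)."""
        return cls(density=np.asarray(concentration, dtype=float) * LITERS_PER_M3
                   if np.ndim(concentration) else float(concentration) * LITERS_PER_M3,
                   speed=speed)


@dataclass(frozen=True)
class EncounterRate:
    """An encounter rate with an explicit time unit.

    ``value`` is encounters per individual per unit time (scalar or array);
    ``unit`` is ``"per-second"`` or ``"per-hour"``.
    """

    value: _ArrayLike
    unit: str = "per-second"

    _UNITS = ("per-second", "per-hour")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValidationError(f"unknown rate unit {self.unit!r}")
        if np.any(np.asarray(self.value) < 0):
            raise ValidationError("encounter rate must be >= 0")

    def to_per_hour(self) -> "EncounterRate":
        if self.unit == "per-hour":
            return self
        return EncounterRate(self.value * SECONDS_PER_HOUR, "per-hour")

    def to_per_second(self) -> "EncounterRate":
        if self.unit == "per-second":
            return self
        return EncounterRate(self.value / SECONDS_PER_HOUR, "per-second")


def _gs_value(radius: float, density: _ArrayLike, x: float, y: float) -> _ArrayLike:
    """GS rate in s^-1 with the singular x*y denominator handled analytically.

    For min(x, y) <= SPEED_TOL the bracket limit is 6*max(x, y), giving
    pi R^2 N max(x, y); both stationary is undefined (no relative motion).
    """
    geom = math.pi * radius ** 2
    if x <= SPEED_TOL and y <= SPEED_TOL:
        raise DegenerateMotionError(
            "both searcher and particle speeds are zero: no relative motion, "
            "the encounter rate is undefined")
    if min(x, y) <= SPEED_TOL:
        return geom * density * max(x, y)
    bracket = ((x + y) ** 3 - abs(x - y) ** 3) / (x * y)
    return geom * density * bracket / 6.0


def gs_rate(swimmer: Swimmer, particles: ParticleField) -> EncounterRate:
    """Gerritsen–Strickler encounter rate under calm conditions, per second.

    Raises
    ------
    DegenerateMotionError
        If both the swimmer and the particles are stationary.
    """
    return EncounterRate(
        _gs_value(swimmer.radius, particles.density, particles.speed, swimmer.speed))


def effective_speed(v: float, w: float) -> float:
    """Effective speed sqrt(v^2 + w^2) of an agent in turbulence of RMS velocity w."""
    if not v >= 0:
        raise ValidationError(f"speed must be >= 0, got {v}")
    if not w >= 0:
        raise ValidationError(f"turbulent velocity must be >= 0, got {w}")
    return math.hypot(v, w)


def ro_rate(swimmer: Swimmer, particles: ParticleField, w: float) -> EncounterRate:
    """Rothschild–Osborn turbulence-augmented encounter rate, per second.

    Equals :func:`gs_rate` evaluated with both speeds replaced by their
    effective speeds; reduces exactly to the GS rate at w = 0 and dominates
    it for every w > 0.
    """
    y_eff = effective_speed(swimmer.speed, w)
    x_eff = effective_speed(particles.speed, w)
    return EncounterRate(_gs_value(swimmer.radius, particles.density, x_eff, y_eff))


def turbulence_multiplier(y: float, x: float, w: float) -> float:
    """Ratio of the RO to the GS encounter rate at turbulent velocity w.

    Independent of R and N (both cancel), >= 1, and equal to 1 at w = 0.
    """
    swimmer = Swimmer("_ratio", speed=y, radius=1.0)
    particles = ParticleField(density=1.0, speed=x)
    calm = gs_rate(swimmer, particles).value
    turbulent = ro_rate(swimmer, particles, w).value
    return float(turbulent / calm)


#: Copepod cruising speed that reproduces the published encounter rates
#: (6.2 cm s^-1); the literature-cited 6.2 mm s^-1 is available via
#: ``taxon_registry(copepod_speed_as_printed=True)``.  See docs/methods.md.
COPEPOD_SPEED_DEFAULT = 0.062
COPEPOD_SPEED_AS_PRINTED = 0.0062


def taxon_registry(copepod_speed_as_printed: bool = False) -> Mapping[str, Swimmer]:
    """Built-in swimmer parameters for the three study taxa.

    ======================  ==========  ===============
    taxon                   speed y     radius R
    ======================  ==========  ===============
    copepod (A. tonsa)      0.062 m/s   0.4 mm
    chaetognath             0.04 m/s    20 mm
    luciferid               0.016 m/s   20 mm
    ======================  ==========  ===============

    The mapping is read-only; copy it (``dict(...)``) to add custom swimmers.
    """
    copepod_speed = (COPEPOD_SPEED_AS_PRINTED if copepod_speed_as_printed
                     else COPEPOD_SPEED_DEFAULT)
    return MappingProxyType({
        "copepod": Swimmer("copepod", speed=copepod_speed, radius=4.0e-4),
        "chaetognath": Swimmer("chaetognath", speed=0.04, radius=0.02),
        "luciferid": Swimmer("luciferid", speed=0.016, radius=0.02),
    })
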