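"""Spherical-approximation geometry and volume-unit handling.

Casein microparticles (CMPs) stay spherical throughout swelling and
shrinkage, so the projected circular area A measured under the microscope,
the particle volume V and the radius R are tied together by

    A = pi * R**2,   V = (4/3) * pi * R**3,   hence   A = 3 * V / (4 * R).

All conversions in the package go through this module. Canonical internal
units are micrometres and seconds: areas in µm², volumes in µm³ (1 µm³ is
exactly 1 fL; 1 pL is 1000 fL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParticleState",
    "volume_to_area",
    "area_to_volume",
    "volume_to_radius",
    "convert_volume_units",
    "VOLUME_UNITS",
]

#: Scale factors to femtolitres (≡ µm³).
VOLUME_UNITS = {
    "fL": 1.0,
    "um3": 1.0,
    "µm3": 1.0,
    "um^3": 1.0,
    "pL": 1000.0,
}

_REL_TOL = 1e-12


def _require_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def volume_to_radius(volume):
    """Radius (µm) of a sphere of the given volume (µm³)."""
    _require_positive("volume", volume)
    return np.cbrt(3.0 * np.asarray(volume, dtype=float) / (4.0 * math.pi))


def volume_to_area(volume):
    """Projected circular area (µm²) of a sphere of the given volume (µm³).

    Evaluates ``pi**(1/3) * (3 * V / 4)**(2/3)``; scalar in, scalar out.
    """
    _require_positive("volume", volume)
    v = np.asarray(volume, dtype=float)
    out = np.cbrt(math.pi) * np.cbrt(3.0 * v / 4.0) ** 2
    return float(out) if np.isscalar(volume) or out.ndim == 0 else out


def area_to_volume(area):
    """Volume (µm³) of a sphere with projected area (µm²); inverse of
    :func:`volume_to_area`."""
    _require_positive("area", area)
    a = np.asarray(area, dtype=float)
    out = (4.0 / 3.0) * np.sqrt(a**3 / math.pi)
    return float(out) if np.isscalar(area) or out.ndim == 0 else out


def convert_volume_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact rescaling between volume units (fL ≡ µm³; 1 pL = 1000 fL)."""
    try:
        scale_from = VOLUME_UNITS[from_unit]
        scale_to = VOLUME_UNITS[to_unit]
    except KeyError as exc:
        raise KeyError(
            f"unknown volume unit {exc.args[0]!r}; known: {sorted(VOLUME_UNITS)}"
        ) from None
    return value * scale_from / scale_to


@dataclass(frozen=True)
class ParticleState:
    """Geometric state of one spherical CMP.

    volume in µm³ (≡ fL), radius in µm, area in µm². The three fields are
    mutually consistent; construct via :meth:`from_volume`,
    :meth:`from_area` or :meth:`from_radius`.
    """

    volume: float
    radius: float
    area: float

    def __post_init__(self) -> None:
        for name in ("volume", "radius", "area"):
            _require_positive(name, getattr(self, name))
        if not math.isclose(self.area, math.pi * self.radius**2, rel_tol=_REL_TOL):
            raise ValueError("area inconsistent with radius (A != pi R^2)")
        if not math.isclose(
            self.volume, (4.0 / 3.0) * math.pi * self.radius**3, rel_tol=_REL_TOL
        ):
            raise ValueError("volume inconsistent with radius (V != 4/3 pi R^3)")

    @classmethod
    def from_radius(cls, radius: float) -> "ParticleState":
        _require_positive("radius", radius)
        return cls(
            volume=(4.0 / 3.0) * math.pi * radius**3,
            radius=radius,
            area=math.pi * radius**2,
        )

    @classmethod
    def from_volume(cls, volume: float) -> "ParticleState":
        return cls.from_radius(float(volume_to_radius(volume)))

    @classmethod
    def from_area(cls, area: float) -> "ParticleState":
        _require_positive("area", area)
        return cls.from_radius(math.sqrt(area / math.pi))
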