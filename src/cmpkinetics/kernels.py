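"""Time-dependent kernels shared by the closed-form models and the simulator.

Three families of building blocks drive the volume balance of a CMP:

* Gaussian pulses ``g(t) = n * exp(-(t - t_plus)**2 / (2 * sigma**2))`` —
  unnormalized bell curves whose amplitude ``n`` carries the units (a rate
  in s⁻¹ when driving a first-order volume flow, a percentage when carving
  dips into the casein solubility curve). The running integral of a pulse
  has the closed form ``sqrt(2*pi)/2 * n * sigma * erf(...)``, which is why
  the acid-shrinkage kinetics solve to products of exponentials of error
  functions. The unnormalized convention is canonical throughout the
  package: the amplitude absorbs any normalization factor.

* On/off gates (step, pulse, ramp-activation) that switch flows according to
  the chronology of the digestion experiment. Gates are right-continuous:
  a step is 0 before its start time and 1 from the start time on; a pulse
  is 1 on the half-open interval [start, end). The ramp used by the
  degradation phase carries no slope of its own (the flow magnitude is set
  by rate coefficients), so it behaves as a unit activation at its start.

* The linear time→pH map for the acidification ramp, anchored at the two
  casein insolubility maxima (pH 6.2 and the isoelectric point pH 4.2), and
  the pH-dependent casein solubility curve, 100% minus two Gaussian dips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import erf

__all__ = [
    "GaussianPulse",
    "GateSchedule",
    "PhScheduleParams",
    "SolubilityParams",
    "gaussian_value",
    "gaussian_integral",
    "gate_value",
    "time_to_ph",
    "solubility_curve",
]

_SQRT2 = math.sqrt(2.0)
_HALF_SQRT_2PI = math.sqrt(2.0 * math.pi) / 2.0


@dataclass(frozen=True)
class GaussianPulse:
    """Unnormalized Gaussian kernel (n, center, sigma).

    ``n`` is the peak value (units set by context), ``center`` the peak
    position (s on the time axis, pH units on the pH axis), ``sigma`` a
    standard-deviation-like width in the same unit as ``center``.
    """

    n: float
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.n < 0:
            raise ValueError(f"amplitude n must be >= 0, got {self.n}")

    def value(self, t):
        t = np.asarray(t, dtype=float)
        out = self.n * np.exp(-((t - self.center) ** 2) / (2.0 * self.sigma**2))
        return float(out) if out.ndim == 0 else out

    def integral(self, t0: float, t1: float) -> float:
        """Exact integral of :meth:`value` over [t0, t1] (erf closed form)."""
        if t0 > t1:
            raise ValueError("require t0 <= t1")
        z0 = (t0 - self.center) / (_SQRT2 * self.sigma)
        z1 = (t1 - self.center) / (_SQRT2 * self.sigma)
        return _HALF_SQRT_2PI * self.n * self.sigma * float(erf(z1) - erf(z0))

    def to_dict(self) -> dict:
        return {"n": self.n, "t_plus": self.center, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianPulse":
        return cls(n=d["n"], center=d["t_plus"], sigma=d["sigma"])


def gaussian_value(pulse: GaussianPulse, t):
    """Kernel value ``n * exp(-(t - center)**2 / (2 sigma**2))``."""
    return pulse.value(t)


def gaussian_integral(pulse: GaussianPulse, t0: float, t1: float) -> float:
    """Closed-form integral of the pulse over [t0, t1]."""
    return pulse.integral(t0, t1)


@dataclass(frozen=True)
class GateSchedule:
    """Right-continuous 0/1 gate: ``step``/``ramp`` switch on at *start*
    (held on); ``pulse`` is on over the half-open window [start, end)."""

    kind: str
    start: float
    end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "pulse", "ramp"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "pulse":
            if self.end is None or not self.start < self.end:
                raise ValueError("pulse gate requires start < end")
        elif self.end is not None:
            raise ValueError(f"{self.kind} gate takes no end time")

    def value(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "pulse":
            out = np.where((t >= self.start) & (t < self.end), 1.0, 0.0)
        else:
            out = np.where(t >= self.start, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "start": self.start}
        if self.end is not None:
            d["end"] = self.end
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateSchedule":
        return cls(kind=d["kind"], start=d["start"], end=d.get("end"))


def gate_value(gate: GateSchedule, t):
    """0/1 gate state at time t (right-continuous at switch times)."""
    return gate.value(t)


@dataclass(frozen=True)
class PhScheduleParams:
    """Anchors of the linear acidification ramp.

    The pH is assumed to fall linearly with time under gastric conditions;
    the two anchors are the times at which the two insolubility maxima
    (pH 6.2 and the isoelectric point, pH 4.2) are crossed.
    """

    t1_plus: float
    t2_plus: float
    ph1_plus: float = 6.2
    ph2_plus: float = 4.2

    def __post_init__(self) -> None:
        if not self.t1_plus < self.t2_plus:
            raise ValueError("require t1_plus < t2_plus")
        if not self.ph1_plus > self.ph2_plus:
            raise ValueError("require ph1_plus > ph2_plus (acidification)")


def time_to_ph(params: PhScheduleParams, t):
    """Linear time→pH map through the two anchors; extrapolates linearly
    outside [t1_plus, t2_plus] (annotation use only)."""
    t = np.asarray(t, dtype=float)
    frac = (t - params.t1_plus) / (params.t2_plus - params.t1_plus)
    out = params.ph1_plus - frac * (params.ph1_plus - params.ph2_plus)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SolubilityParams:
    """Casein solubility vs pH: 100% plus an offset, minus two Gaussian
    insolubility dips (one near pH 6, one at the isoelectric point)."""

    pulses: Tuple[GaussianPulse, GaussianPulse]
    const: float = 0.0


def solubility_curve(params: SolubilityParams, ph):
    """Solubility (%) at the given pH."""
    ph = np.asarray(ph, dtype=float)
    out = 100.0 + params.const
    for pulse in params.pulses:
        out = out - pulse.value(ph)
    return float(out) if np.ndim(out) == 0 else out
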