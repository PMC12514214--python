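"""Closed-form volume kinetics for the acid-shrinkage and pepsin-decay phases.

Phase I (acid-induced two-step shrinkage). The solvent outflow is taken
proportional to the current volume times the degree of casein insolubility,
modelled as two Gaussian pulses on the time axis (one per insolubility
maximum crossed during acidification). Integrating dV/V = -(g1 + g2) dt
gives

    V(t) = V0 * exp(- sqrt(2*pi)/2 * n1 * s1 * erf((t - t1)/(sqrt(2) s1))
                    - sqrt(2*pi)/2 * n2 * s2 * erf((t - t2)/(sqrt(2) s2)))

Note that V0 is a fit constant anchored mid-curve (where both erf terms
vanish), not the volume at t = 0: well before both pulses each erf is ~ -1,
so V(0) ≈ V0 * exp(+sqrt(2*pi)/2 * (n1 s1 + n2 s2)) > V0. Both V(0) and the
total shrink factor V(inf)/V(0) = exp(-sqrt(2*pi) * (n1 s1 + n2 s2)) are
exposed as derived quantities.

Phase III (pepsin-induced decay of a pre-acidified particle). A weak
erf-shaped contraction — surface hydrolysis of the kappa-casein layer —
precedes bulk proteolysis; once pepsin has penetrated the network the
volume decays exponentially to a plateau:

    V(t) = V0 * exp(-sqrt(2*pi)/2 * n3 * s3 * erf((t - t3)/(sqrt(2) s3)))
                                                     for t <  breakpoint
    V(t) = V4 * exp(-t / t4) + V_inf                 for t >= breakpoint

The two branches are fitted independently (no continuity is enforced at the
breakpoint, 147 s by default); the jump is reported as a diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .kernels import GaussianPulse

__all__ = [
    "Phase1Params",
    "Phase3Params",
    "eval_phase1",
    "eval_phase3",
    "phase3_rate",
    "phase3_plateau_fraction",
]

_SQRT2 = math.sqrt(2.0)
_HALF_SQRT_2PI = math.sqrt(2.0 * math.pi) / 2.0


@dataclass(frozen=True)
class Phase1Params:
    """Parameters of the two-step acid-shrinkage closed form.

    ``v0`` is the mid-curve reference volume (same unit as the data it was
    fitted to, or 1.0 for relative-volume fits); ``pulse1``/``pulse2`` are
    the insolubility pulses (amplitudes in s⁻¹, centers/widths in s).
    """

    v0: float
    pulse1: GaussianPulse
    pulse2: GaussianPulse

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if not self.pulse1.center < self.pulse2.center:
            raise ValueError("require pulse1 center < pulse2 center")

    @property
    def initial_volume(self) -> float:
        """V at t = 0 implied by the closed form (exceeds v0)."""
        return float(eval_phase1(self, 0.0))

    @property
    def total_shrink_factor(self) -> float:
        """V(inf)/V(0) = exp(-sqrt(2*pi) * (n1*s1 + n2*s2))."""
        s = self.pulse1.n * self.pulse1.sigma + self.pulse2.n * self.pulse2.sigma
        return math.exp(-2.0 * _HALF_SQRT_2PI * s)

    def to_dict(self) -> dict:
        return {
            "v0": self.v0,
            "pulse1": self.pulse1.to_dict(),
            "pulse2": self.pulse2.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phase1Params":
        return cls(
            v0=d["v0"],
            pulse1=GaussianPulse.from_dict(d["pulse1"]),
            pulse2=GaussianPulse.from_dict(d["pulse2"]),
        )


@dataclass(frozen=True)
class Phase3Params:
    """Parameters of the piecewise pepsin-decay model (volumes in pL)."""

    v0: float
    pulse3: GaussianPulse
    v4: float
    t4: float
    v_inf: float
    breakpoint: float = 147.0

    def __post_init__(self) -> None:
        for name in ("v0", "v4", "t4", "v_inf", "breakpoint"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "v0": self.v0,
            "pulse3": self.pulse3.to_dict(),
            "v4": self.v4,
            "t4": self.t4,
            "v_inf": self.v_inf,
            "breakpoint": self.breakpoint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phase3Params":
        return cls(
            v0=d["v0"],
            pulse3=GaussianPulse.from_dict(d["pulse3"]),
            v4=d["v4"],
            t4=d["t4"],
            v_inf=d["v_inf"],
            breakpoint=d.get("breakpoint", 147.0),
        )


def _erf_term(pulse: GaussianPulse, t):
    z = (np.asarray(t, dtype=float) - pulse.center) / (_SQRT2 * pulse.sigma)
    return _HALF_SQRT_2PI * pulse.n * pulse.sigma * erf(z)


def eval_phase1(params: Phase1Params, t):
    """Closed-form two-step shrinkage volume at time t (unit of ``v0``)."""
    out = params.v0 * np.exp(-_erf_term(params.pulse1, t) - _erf_term(params.pulse2, t))
    return float(out) if np.ndim(out) == 0 else out


def eval_phase3(params: Phase3Params, t):
    """Piecewise pepsin-decay volume (pL) at time t.

    erf branch for t < breakpoint, exponential-to-plateau branch for
    t >= breakpoint. The exponential uses absolute time (V4 e^{-t/t4}), so
    no continuity holds at the breakpoint unless the fit happens to align.
    """
    t = np.asarray(t, dtype=float)
    branch1 = params.v0 * np.exp(-_erf_term(params.pulse3, t))
    branch2 = params.v4 * np.exp(-t / params.t4) + params.v_inf
    out = np.where(t < params.breakpoint, branch1, branch2)
    return float(out) if out.ndim == 0 else out


def phase3_rate(params: Phase3Params) -> float:
    """First-order decay rate 1/t4 (s⁻¹) of the proteolysis branch."""
    return 1.0 / params.t4


def phase3_plateau_fraction(params: Phase3Params, reference_volume: float) -> float:
    """Plateau volume V_inf as a fraction of a chosen reference volume."""
    if reference_volume <= 0:
        raise ValueError("reference_volume must be > 0")
    return params.v_inf / reference_volume
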