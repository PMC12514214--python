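"""Stock-and-flow simulator of the full three-phase digestion kinetics.

One stock — the particle volume V (fL) — is changed only by three gated
flows (no volume sources or sinks inside the particle):

    dV/dt = -I_V1 + I_V2 - I_V3

* ``I_V1`` (phase I, acid shrinkage): first-order outflow driven by the two
  insolubility pulses, V * (g1(t) + g2(t)), active until the shrinkage
  minimum at the second pulse center (t = swell_start), where the solvent
  flow reverses direction.
* ``I_V2`` (phase II, anomalous swelling): inflow gated by a pulse on
  [swell_start, degradation_start). The tail of the second insolubility
  pulse re-enters as inflow, a sustained superlinear swelling term
  RC1 * V * (V/V_ref)**(nx - 1) drives the expansion, and a third Gaussian
  pulse — surface proteolysis of the kappa-casein layer — subtracts volume
  from t = surface_shrink_start until degradation starts, throttling the
  swelling towards the end of the phase. The (V/V_ref)**(nx-1) factor keeps
  RC1 in s⁻¹ for any exponent nx; V_ref defaults to the initial volume.
* ``I_V3`` (phase III, enzymatic decay): activated at degradation_start,
  RC2 * V - RC3, a linear relaxation whose fixed point V_inf = RC3/RC2 sets
  the final plateau. The corresponding steady-state projection area is
  pi**(1/3) * (3/4 * RC3/RC2)**(2/3).

Integration is explicit fixed-step Euler (default dt = 0.25 s) with the
area recorded at every step via the spherical approximation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .geometry import volume_to_area
from .kernels import GaussianPulse, GateSchedule

__all__ = [
    "SystemModelConfig",
    "Trajectory",
    "flows",
    "simulate",
    "steady_state_area",
    "steady_state_volume",
]


@dataclass(frozen=True)
class SystemModelConfig:
    """Full parameter set and event chronology of the three-phase model.

    Volumes in fL, times in s, RC1/RC2 in s⁻¹, RC3 in fL·s⁻¹; ``nx`` is the
    dimensionless swelling exponent and ``swell_reference`` the reference
    volume of the swelling power law (defaults to ``v0``).
    """

    v0: float
    gauss1: GaussianPulse
    gauss2: GaussianPulse
    gauss3: GaussianPulse
    rc1: float
    nx: float
    rc2: float
    rc3: float
    swell_start: float
    surface_shrink_start: float
    degradation_start: float
    dt: float = 0.25
    t_end: float = 2400.0
    volume_floor: float = 1e-6
    swell_reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.dt <= 0 or self.volume_floor <= 0:
            raise ValueError("v0, dt and volume_floor must be > 0")
        for name in ("rc1", "rc2", "rc3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (
            self.swell_start < self.surface_shrink_start < self.degradation_start
        ):
            raise ValueError(
                "require swell_start < surface_shrink_start < degradation_start"
            )
        if self.t_end <= self.degradation_start:
            raise ValueError("t_end must exceed degradation_start")
        if self.swell_reference is not None and self.swell_reference <= 0:
            raise ValueError("swell_reference must be > 0")

    @property
    def swell_ref(self) -> float:
        return self.v0 if self.swell_reference is None else self.swell_reference

    # Gates implementing the chronology of events.
    @property
    def swell_pulse(self) -> GateSchedule:
        return GateSchedule("pulse", self.swell_start, self.degradation_start)

    @property
    def surface_shrink_pulse(self) -> GateSchedule:
        return GateSchedule("pulse", self.surface_shrink_start, self.degradation_start)

    @property
    def degradation_ramp(self) -> GateSchedule:
        return GateSchedule("ramp", self.degradation_start)

    def to_dict(self) -> dict:
        d = {
            "v0": self.v0,
            "gauss1": self.gauss1.to_dict(),
            "gauss2": self.gauss2.to_dict(),
            "gauss3": self.gauss3.to_dict(),
            "rc1": self.rc1,
            "nx": self.nx,
            "rc2": self.rc2,
            "rc3": self.rc3,
            "swell_start": self.swell_start,
            "surface_shrink_start": self.surface_shrink_start,
            "degradation_start": self.degradation_start,
            "dt": self.dt,
            "t_end": self.t_end,
            "volume_floor": self.volume_floor,
        }
        if self.swell_reference is not None:
            d["swell_reference"] = self.swell_reference
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemModelConfig":
        kwargs = dict(d)
        for key in ("gauss1", "gauss2", "gauss3"):
            kwargs[key] = GaussianPulse.from_dict(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "SystemModelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def with_overrides(self, **kwargs) -> "SystemModelConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """Euler trajectory on the uniform grid: volumes (fL), areas (µm²) and
    the per-step flow decomposition (fL·s⁻¹, evaluated at each grid time)."""

    times: np.ndarray
    volumes: np.ndarray
    areas: np.ndarray
    iv1: np.ndarray
    iv2: np.ndarray
    iv3: np.ndarray
    floor_hits: int = 0

    @property
    def final_volume(self) -> float:
        return float(self.volumes[-1])

    @property
    def final_area(self) -> float:
        return float(self.areas[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "volume_fL": self.volumes,
                "area_um2": self.areas,
                "iv1": self.iv1,
                "iv2": self.iv2,
                "iv3": self.iv3,
            }
        )


def _swell_flow(config: SystemModelConfig, v: float) -> float:
    return config.rc1 * v * (v / config.swell_ref) ** (config.nx - 1.0)


def flows(
    config: SystemModelConfig, t: float, v: float
) -> Tuple[float, float, float]:
    """Flow decomposition (I_V1, I_V2, I_V3) in fL·s⁻¹ at time t, volume v."""
    if v <= 0:
        raise ValueError("volume must be > 0")
    g1 = config.gauss1.value(t)
    g2 = config.gauss2.value(t)
    g3 = config.gauss3.value(t)
    iv1 = v * (g1 + g2) if t < config.swell_start else 0.0
    p1 = config.swell_pulse.value(t)
    p2 = config.surface_shrink_pulse.value(t)
    iv2 = p1 * (v * g2 + _swell_flow(config, v)) - p2 * v * g3
    iv3 = config.degradation_ramp.value(t) * (config.rc2 * v - config.rc3)
    return float(iv1), float(iv2), float(iv3)


class IntegrationError(RuntimeError):
    """Raised when the Euler state becomes non-finite."""


def simulate(config: SystemModelConfig) -> Trajectory:
    """Integrate the volume balance by explicit Euler from t = 0 (medium
    exchange) to ``t_end``, recording every step.

    The update is ``V[k+1] = V[k] + dt * (-I_V1 + I_V2 - I_V3)`` with the
    flows evaluated at the left endpoint of each step, so the recorded flow
    decomposition reproduces each volume increment exactly. Volumes are
    clipped at ``volume_floor`` (with a warning) rather than going
    non-positive.
    """
    n_steps = int(round(config.t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt

    # Kernel/gate values depend only on time: precompute on the grid.
    g1 = config.gauss1.value(times)
    g2 = config.gauss2.value(times)
    g3 = config.gauss3.value(times)
    out_mask = (times < config.swell_start).astype(float)
    p1 = config.swell_pulse.value(times)
    p2 = config.surface_shrink_pulse.value(times)
    r2 = config.degradation_ramp.value(times)
    g12 = (g1 + g2) * out_mask

    rc1, nx, rc2, rc3 = config.rc1, config.nx, config.rc2, config.rc3
    inv_ref = 1.0 / config.swell_ref
    dt = config.dt

    volumes = np.empty(n_steps + 1)
    iv1_arr = np.empty(n_steps + 1)
    iv2_arr = np.empty(n_steps + 1)
    iv3_arr = np.empty(n_steps + 1)

    v = float(config.v0)
    floor_hits = 0
    for k in range(n_steps + 1):
        iv1 = v * g12[k]
        iv2 = 0.0
        if p1[k]:
            iv2 = v * g2[k] + rc1 * v * (v * inv_ref) ** (nx - 1.0)
        if p2[k]:
            iv2 -= v * g3[k]
        iv3 = r2[k] * (rc2 * v - rc3)
        if not (math.isfinite(iv1) and math.isfinite(iv2) and math.isfinite(iv3)):
            raise IntegrationError(
                f"non-finite flow at step {k} (t = {times[k]:.3f} s, V = {v:.6g} fL)"
            )
        volumes[k] = v
        iv1_arr[k] = iv1
        iv2_arr[k] = iv2
        iv3_arr[k] = iv3
        if k < n_steps:
            v = v + dt * (-iv1 + iv2 - iv3)
            if not math.isfinite(v):
                raise IntegrationError(
                    f"non-finite volume after step {k} (t = {times[k]:.3f} s)"
                )
            if v < config.volume_floor:
                v = config.volume_floor
                floor_hits += 1

    if floor_hits:
        warnings.warn(
            f"volume clipped at floor {config.volume_floor} fL on "
            f"{floor_hits} step(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    return Trajectory(
        times=times,
        volumes=volumes,
        areas=volume_to_area(volumes),
        iv1=iv1_arr,
        iv2=iv2_arr,
        iv3=iv3_arr,
        floor_hits=floor_hits,
    )


def steady_state_volume(config: SystemModelConfig) -> float:
    """Fixed point RC3/RC2 (fL) of the degradation flow."""
    if config.rc2 == 0:
        raise ZeroDivisionError("no steady state: rc2 == 0")
    return config.rc3 / config.rc2


def steady_state_area(config: SystemModelConfig) -> float:
    """Final projection area pi**(1/3) * (3/4 * RC3/RC2)**(2/3) in µm²."""
    return float(volume_to_area(steady_state_volume(config)))
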