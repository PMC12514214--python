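"""Synthetic microscope-like area time series with known ground truth.

The generator emulates what the flow-cell experiment measures: the
projected area of one spherical CMP sampled at 2 frames per second, for
each of the three experimental scenarios:

* ``sgf_pepsin`` — medium exchanged for SGF at pH 2 with pepsin; the full
  three-phase curve produced by the stock-and-flow simulator.
* ``water_ph2`` — acidification with ultrapure water, no pepsin; the
  two-step closed-form shrinkage, optionally followed by a simple
  exponential expansion segment standing in for the dissolution of the
  particle (the expansion is a generator convenience to exercise window
  selection and carries no fitted reference values).
* ``preacidified_pepsin`` — particle pre-equilibrated in SGF at pH 2, then
  exposed to pepsin; the piecewise erf/exponential decay model.

Measurement noise is multiplicative lognormal on the area: segmentation
error scales with particle size. The log-noise is centred (median-unbiased);
the mean of the noisy area exceeds the noiseless curve by the lognormal
correction factor exp(log(1 + cv²)/2) = sqrt(1 + cv²), i.e. by 0.005% at the
default cv of 1% — negligible against the sampling error of any realistic
replicate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from . import presets
from .geometry import volume_to_area
from .phases import Phase1Params, Phase3Params, eval_phase1, eval_phase3
from .systemdynamics import SystemModelConfig, simulate

__all__ = [
    "ExpansionSegment",
    "ScenarioSpec",
    "KineticsSeries",
    "generate",
    "scenario_defaults",
    "SCENARIOS",
]

SCENARIOS = ("sgf_pepsin", "water_ph2", "preacidified_pepsin")


@dataclass(frozen=True)
class ExpansionSegment:
    """Exponential late-stage expansion appended to the water scenario:
    volume multiplied by exp(rate * (t - start)) for t > start."""

    start: float
    rate: float

    def factor(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(self.rate * np.clip(t - self.start, 0.0, None))


@dataclass(frozen=True)
class KineticsSeries:
    """Sampled (time, area) trajectory of one particle.

    ``times`` in s (strictly increasing), ``areas`` in µm² (> 0).
    ``noiseless`` carries the underlying model curve for synthetic series.
    """

    times: np.ndarray
    areas: np.ndarray
    provenance: str = "synthetic"
    scenario: Optional[str] = None
    seed: Optional[int] = None
    noiseless: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "areas", areas)
        if times.shape != areas.shape or times.ndim != 1:
            raise ValueError("times and areas must be 1-D arrays of equal length")
        if len(times) and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(areas > 0):
            raise ValueError("areas must be strictly positive")
        if self.provenance not in ("measured", "synthetic"):
            raise ValueError("provenance must be 'measured' or 'synthetic'")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, start: float, end: float) -> "KineticsSeries":
        """Sub-series restricted to start <= t < end."""
        mask = (self.times >= start) & (self.times < end)
        return replace(
            self,
            times=self.times[mask],
            areas=self.areas[mask],
            noiseless=None if self.noiseless is None else self.noiseless[mask],
        )


GroundTruth = Union[Phase1Params, Phase3Params, SystemModelConfig]


@dataclass(frozen=True)
class ScenarioSpec:
    """Generation recipe: scenario tag, ground-truth parameters, duration
    (s), frame rate (Hz), multiplicative noise CV, and RNG seed."""

    scenario: str
    ground_truth: GroundTruth
    duration: float
    frame_rate: float = 2.0
    noise_cv: float = 0.01
    seed: int = 0
    # water_ph2 only: absolute volume scale (fL) and optional dissolution
    # expansion; the reference fit is on relative volume (v0 = 1).
    volume_scale_fL: float = 1.0
    expansion: Optional[ExpansionSegment] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; known: {SCENARIOS}")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def scenario_defaults(scenario: str) -> ScenarioSpec:
    """Default generation recipe with the reference parameter values as
    ground truth (seeded, 2 fps, 1% multiplicative noise)."""
    if scenario == "sgf_pepsin":
        return ScenarioSpec(
            scenario=scenario,
            ground_truth=presets.system_sgf_pepsin(),
            duration=2400.0,
        )
    if scenario == "water_ph2":
        return ScenarioSpec(
            scenario=scenario,
            ground_truth=presets.phase1_water_ph2(),
            duration=900.0,
            volume_scale_fL=200.0,
            expansion=ExpansionSegment(start=680.0, rate=0.003),
        )
    if scenario == "preacidified_pepsin":
        return ScenarioSpec(
            scenario=scenario,
            ground_truth=presets.phase3_preacidified(),
            duration=900.0,
        )
    raise KeyError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")


def _noiseless_areas(spec: ScenarioSpec, times: np.ndarray) -> np.ndarray:
    if spec.scenario == "sgf_pepsin":
        config = spec.ground_truth
        if not isinstance(config, SystemModelConfig):
            raise TypeError("sgf_pepsin ground truth must be a SystemModelConfig")
        if config.t_end < spec.duration:
            config = config.with_overrides(t_end=spec.duration)
        traj = simulate(config)
        idx = np.rint(times / config.dt).astype(int)
        idx = np.clip(idx, 0, len(traj.areas) - 1)
        return traj.areas[idx]
    if spec.scenario == "water_ph2":
        params = spec.ground_truth
        if not isinstance(params, Phase1Params):
            raise TypeError("water_ph2 ground truth must be Phase1Params")
        volumes = eval_phase1(params, times) * spec.volume_scale_fL / params.v0
        if spec.expansion is not None:
            volumes = volumes * spec.expansion.factor(times)
        return volume_to_area(volumes)
    if spec.scenario == "preacidified_pepsin":
        params = spec.ground_truth
        if not isinstance(params, Phase3Params):
            raise TypeError("preacidified_pepsin ground truth must be Phase3Params")
        volumes_pl = eval_phase3(params, times)
        return volume_to_area(volumes_pl * 1000.0)  # pL -> fL = µm³
    raise ValueError(f"unknown scenario {spec.scenario!r}")


def generate(spec: ScenarioSpec) -> KineticsSeries:
    """Sample the scenario's model curve on the uniform frame grid and apply
    seeded multiplicative lognormal noise.

    The grid is ``0, 1/f, 2/f, ..., duration`` inclusive (duration * f + 1
    samples at frame rate f). With ``noise_cv = 0`` the returned areas equal
    the model curve exactly; the noiseless curve is always attached.
    """
    n_frames = int(round(spec.duration * spec.frame_rate))
    times = np.arange(n_frames + 1) / spec.frame_rate
    noiseless = _noiseless_areas(spec, times)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        areas = noiseless * np.exp(rng.normal(0.0, sigma, size=noiseless.shape))
    else:
        areas = noiseless.copy()
    return KineticsSeries(
        times=times,
        areas=areas,
        provenance="synthetic",
        scenario=spec.scenario,
        seed=spec.seed,
        noiseless=noiseless,
    )
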