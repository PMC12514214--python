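"""Parameter estimation for the phase models and the full system model.

Three fitting routes mirror how the reference analysis treats the data:

* :func:`fit_phase1` — constrained nonlinear least squares of the two-step
  acid-shrinkage closed form against *relative volume* (the series is
  converted from area to volume and normalized to the start of the fitting
  window). The width of the first pulse and the center of the second are
  conventionally fixed; the center of the second pulse defaults to the
  argmin of a 5-point moving average of the series — a reproducible
  surrogate for reading the shrinkage minimum off the plot.
* :func:`fit_phase3` — independent segment fits of the piecewise
  pepsin-decay model: the erf branch before the breakpoint (width fixed)
  and the exponential-to-plateau branch after it, on absolute volume. The
  discontinuity across the breakpoint is reported as a diagnostic.
* :func:`fit_system` — seeded differential evolution over a bounded subset
  of the stock-and-flow parameters, minimizing squared *area* residuals of
  the forward Euler simulation sampled onto the data grid.

All routes return a :class:`FitResult` with point estimates, the residual
sum of squares, R² and a loss trace. No uncertainty quantification is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .geometry import area_to_volume
from .kernels import GaussianPulse
from .phases import Phase1Params, eval_phase1
from .synthetic import KineticsSeries
from .systemdynamics import SystemModelConfig, simulate

__all__ = [
    "FitSpec",
    "FitResult",
    "fit_phase1",
    "fit_phase3",
    "fit_system",
    "r_squared",
]

PHASE1_PARAMS = ("v0", "n1", "sigma1", "t1_plus", "n2", "sigma2", "t2_plus")
PHASE3_PARAMS = ("v0", "n3", "sigma3", "t3_plus", "v4", "t4", "v_inf", "breakpoint")
SYSTEM_PARAMS = (
    "v0",
    "n1", "t1_plus", "sigma1",
    "n2", "t2_plus", "sigma2",
    "n3", "t3_plus", "sigma3",
    "rc1", "nx", "rc2", "rc3",
    "swell_start", "surface_shrink_start", "degradation_start",
)

_DEFAULT_FREE = {
    "phase1": ("v0", "n1", "t1_plus", "n2", "sigma2"),
    "phase3": ("v0", "n3", "t3_plus", "v4", "t4", "v_inf"),
}


@dataclass(frozen=True)
class FitSpec:
    """Declarative description of one fit.

    ``free`` and ``fixed`` must be disjoint; names not listed in either fall
    back to model defaults. ``window`` restricts the fit to start <= t < end
    (absolute series time). ``bounds`` are per-parameter (lo, hi) intervals;
    required for every free parameter of the system model. ``seed`` feeds
    the global optimizer. ``options`` passes through optimizer settings
    (ftol / maxiter / popsize / tol).
    """

    model: str
    free: Optional[Sequence[str]] = None
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None
    window: Optional[Tuple[float, float]] = None
    seed: Optional[int] = None
    options: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("phase1", "phase3", "system"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.free is not None:
            overlap = set(self.free) & set(self.fixed)
            if overlap:
                raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")


@dataclass(frozen=True)
class FitResult:
    """Point estimates and goodness-of-fit of one fit."""

    estimates: Dict[str, float]
    residual_sum: float
    r_squared: float
    n_points: int
    converged: bool
    loss_trace: Tuple[float, ...] = ()
    message: str = ""
    #: Volume jump across the breakpoint (phase3 segment fits only).
    discontinuity: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "estimates": dict(self.estimates),
            "residual_sum": self.residual_sum,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
            "message": self.message,
        }
        if self.discontinuity is not None:
            d["discontinuity"] = self.discontinuity
        return d


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (SS_tot about the
    observed mean). Undefined for constant observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot



def _safe_r_squared(observed, predicted) -> float:
    """R² or NaN when the observations are constant (degenerate fit)."""
    try:
        return r_squared(observed, predicted)
    except ValueError:
        return float("nan")

class UnderdeterminedError(ValueError):
    """Fewer data points than free parameters."""


def _moving_average(y: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def _windowed_volumes(
    series: KineticsSeries, window: Optional[Tuple[float, float]]
) -> Tuple[np.ndarray, np.ndarray]:
    t = series.times
    v = area_to_volume(series.areas)
    if window is not None:
        start, end = window
        mask = (t >= start) & (t < end)
        t, v = t[mask], v[mask]
    if len(t) < 2:
        raise UnderdeterminedError("fewer than 2 points in the fitting window")
    return t, v


def _solve_least_squares(residual, x0, lower, upper, options) -> "object":
    return least_squares(
        residual,
        x0=np.asarray(x0, dtype=float),
        bounds=(np.asarray(lower, dtype=float), np.asarray(upper, dtype=float)),
        method="trf",
        ftol=float(options.get("ftol", 1e-10)),
        xtol=float(options.get("xtol", 1e-12)),
        gtol=float(options.get("gtol", 1e-12)),
        max_nfev=int(options.get("max_nfev", 20000)),
    )


def fit_phase1(series: KineticsSeries, spec: FitSpec) -> FitResult:
    """Fit the two-step acid-shrinkage closed form to a series.

    The series is converted to volume and normalized to its value at the
    start of the fitting window; estimates are therefore on relative
    volume. ``sigma1`` must be fixed (the conventional constraint);
    ``t2_plus`` defaults to the smoothed-series argmin when neither free
    nor fixed.
    """
    if spec.model != "phase1":
        raise ValueError("spec.model must be 'phase1'")
    t, v = _windowed_volumes(series, spec.window)
    y = v / v[0]

    fixed = dict(spec.fixed)
    free = list(spec.free) if spec.free is not None else list(_DEFAULT_FREE["phase1"])
    for name in free + list(fixed):
        if name not in PHASE1_PARAMS:
            raise ValueError(f"unknown phase1 parameter {name!r}")
    if "sigma1" not in fixed and "sigma1" not in free:
        raise ValueError("sigma1 must be fixed or free for the phase1 fit")
    if "t2_plus" not in fixed and "t2_plus" not in free:
        # Reproducible surrogate for reading the minimum off the plot.
        smoothed = _moving_average(y)
        fixed["t2_plus"] = float(t[int(np.argmin(smoothed))])
    if len(t) < len(free):
        raise UnderdeterminedError(
            f"{len(t)} points cannot constrain {len(free)} parameters"
        )

    smoothed = _moving_average(y)
    slope = np.gradient(smoothed, t)
    t2_guess = fixed.get("t2_plus", t[int(np.argmin(smoothed))])
    before_t2 = slope.copy()
    before_t2[t >= t2_guess - 20.0] = np.inf  # steepest descent of step 1
    t1_guess = float(t[int(np.argmin(before_t2))]) if np.isfinite(
        before_t2.min()
    ) else float(t[0] + 0.25 * (t[-1] - t[0]))

    start = {
        "v0": float(smoothed[len(t) // 2]),
        "n1": 0.01,
        "sigma1": 11.0,
        "t1_plus": t1_guess,
        "n2": 0.01,
        "sigma2": 30.0,
        "t2_plus": t2_guess,
    }
    span = float(t[-1] - t[0])
    default_bounds = {
        "v0": (1e-3 * y.min(), 1e3 * y.max()),
        "n1": (0.0, 10.0),
        "n2": (0.0, 10.0),
        "sigma1": (0.5, 10.0 * span),
        "sigma2": (0.5, 10.0 * span),
        "t1_plus": (t[0] - span, t[-1] + span),
        "t2_plus": (t[0] - span, t[-1] + span),
    }
    bounds = {**default_bounds, **(spec.bounds or {})}

    def build(theta: np.ndarray) -> Phase1Params:
        p = dict(fixed)
        p.update({name: val for name, val in zip(free, theta)})
        for name in PHASE1_PARAMS:
            p.setdefault(name, start[name])
        return Phase1Params(
            v0=p["v0"],
            pulse1=GaussianPulse(p["n1"], p["t1_plus"], p["sigma1"]),
            pulse2=GaussianPulse(p["n2"], p["t2_plus"], p["sigma2"]),
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        try:
            params = build(theta)
        except ValueError:
            return np.full_like(y, 1e6)
        return eval_phase1(params, t) - y

    x0 = [min(max(start[name], bounds[name][0]), bounds[name][1]) for name in free]
    sol = _solve_least_squares(
        residual,
        x0,
        [bounds[name][0] for name in free],
        [bounds[name][1] for name in free],
        spec.options,
    )
    estimates = dict(fixed)
    estimates.update({name: float(val) for name, val in zip(free, sol.x)})
    pred = y + sol.fun
    return FitResult(
        estimates=estimates,
        residual_sum=float(np.sum(sol.fun**2)),
        r_squared=_safe_r_squared(y, pred),
        n_points=len(t),
        converged=bool(sol.success),
        loss_trace=(float(np.sum(sol.fun**2)),),
        message=str(sol.message),
    )


def fit_phase3(
    series: KineticsSeries, spec: FitSpec, volume_unit: str = "pL"
) -> FitResult:
    """Segmented fit of the piecewise pepsin-decay model.

    The erf branch (t < breakpoint; free: v0, n3, t3_plus; sigma3 fixed,
    default 37 s) and the exponential branch (t >= breakpoint; free: v4,
    t4, v_inf) are fitted independently on absolute volume. Estimates are
    in ``volume_unit`` ('pL' default, 'fL' for raw µm³).
    """
    if spec.model != "phase3":
        raise ValueError("spec.model must be 'phase3'")
    t, v = _windowed_volumes(series, spec.window)
    if volume_unit == "pL":
        v = v / 1000.0
    elif volume_unit != "fL":
        raise ValueError("volume_unit must be 'pL' or 'fL'")

    fixed = dict(spec.fixed)
    breakpoint_ = float(fixed.pop("breakpoint", 147.0))
    sigma3 = float(fixed.pop("sigma3", 37.0))
    free = list(spec.free) if spec.free is not None else list(_DEFAULT_FREE["phase3"])
    if set(free) != set(_DEFAULT_FREE["phase3"]) or fixed:
        unknown = (set(free) | set(fixed)) - set(PHASE3_PARAMS)
        if unknown:
            raise ValueError(f"unknown phase3 parameters {sorted(unknown)}")

    mask1 = t < breakpoint_
    mask2 = ~mask1
    t1, y1 = t[mask1], v[mask1]
    t2, y2 = t[mask2], v[mask2]
    if len(t1) < 3 or len(t2) < 3:
        raise UnderdeterminedError(
            "each branch needs at least as many points as free parameters "
            f"(got {len(t1)} before and {len(t2)} after the {breakpoint_} s breakpoint)"
        )
    bounds = dict(spec.bounds or {})
    options = spec.options

    # erf branch: V0 * exp(-sqrt(2pi)/2 n3 sigma3 erf((t - t3)/(sqrt2 sigma3)))
    def residual1(theta: np.ndarray) -> np.ndarray:
        v0, n3, t3 = theta
        params = Phase1Params(
            v0=v0,
            pulse1=GaussianPulse(n3, t3, sigma3),
            pulse2=GaussianPulse(0.0, t3 + 1.0, sigma3),
        )
        return eval_phase1(params, t1) - y1

    span1 = float(t1[-1] - t1[0]) or 1.0
    b1 = {
        "v0": bounds.get("v0", (1e-6, 1e6)),
        "n3": bounds.get("n3", (0.0, 10.0)),
        "t3_plus": bounds.get("t3_plus", (t1[0] - 2 * span1, t1[-1] + 4 * span1)),
    }
    x0_1 = [float(y1[0]), 0.01, breakpoint_ + sigma3]
    sol1 = _solve_least_squares(
        residual1, x0_1, [b1[k][0] for k in ("v0", "n3", "t3_plus")],
        [b1[k][1] for k in ("v0", "n3", "t3_plus")], options,
    )
    pred1 = y1 + sol1.fun

    # exponential branch: V4 * exp(-t / t4) + V_inf (absolute time)
    def residual2(theta: np.ndarray) -> np.ndarray:
        v4, t4, v_inf = theta
        return v4 * np.exp(-t2 / t4) + v_inf - y2

    span2 = float(t2[-1] - t2[0]) or 1.0
    v_inf0 = float(y2.min())
    t4_0 = span2 / 3.0
    v4_0 = max(float((y2[0] - v_inf0) * math.exp(t2[0] / t4_0)), 1e-9)
    b2 = {
        "v4": bounds.get("v4", (0.0, 1e9)),
        "t4": bounds.get("t4", (1e-3, 100.0 * span2)),
        "v_inf": bounds.get("v_inf", (0.0, 1e6)),
    }
    x0_2 = [
        min(max(v4_0, b2["v4"][0]), b2["v4"][1]),
        min(max(t4_0, b2["t4"][0]), b2["t4"][1]),
        min(max(v_inf0, b2["v_inf"][0]), b2["v_inf"][1]),
    ]
    sol2 = _solve_least_squares(
        residual2, x0_2, [b2[k][0] for k in ("v4", "t4", "v_inf")],
        [b2[k][1] for k in ("v4", "t4", "v_inf")], options,
    )
    pred2 = y2 + sol2.fun

    estimates = {
        "v0": float(sol1.x[0]),
        "n3": float(sol1.x[1]),
        "t3_plus": float(sol1.x[2]),
        "sigma3": sigma3,
        "v4": float(sol2.x[0]),
        "t4": float(sol2.x[1]),
        "v_inf": float(sol2.x[2]),
        "breakpoint": breakpoint_,
    }
    left = float(eval_phase1(
        Phase1Params(
            v0=estimates["v0"],
            pulse1=GaussianPulse(max(estimates["n3"], 0.0), estimates["t3_plus"], sigma3),
            pulse2=GaussianPulse(0.0, estimates["t3_plus"] + 1.0, sigma3),
        ),
        breakpoint_,
    ))
    right = estimates["v4"] * math.exp(-breakpoint_ / max(estimates["t4"], 1e-12)) + estimates["v_inf"]
    residual_sum = float(np.sum(sol1.fun**2) + np.sum(sol2.fun**2))
    obs = np.concatenate([y1, y2])
    pred = np.concatenate([pred1, pred2])
    return FitResult(
        estimates=estimates,
        residual_sum=residual_sum,
        r_squared=_safe_r_squared(obs, pred),
        n_points=len(t),
        converged=bool(sol1.success and sol2.success),
        loss_trace=(residual_sum,),
        message=f"erf branch: {sol1.message}; exp branch: {sol2.message}",
        discontinuity=left - right,
    )


def _apply_system_params(
    config: SystemModelConfig, values: Mapping[str, float]
) -> SystemModelConfig:
    pulses = {
        "gauss1": list(
            (config.gauss1.n, config.gauss1.center, config.gauss1.sigma)
        ),
        "gauss2": list(
            (config.gauss2.n, config.gauss2.center, config.gauss2.sigma)
        ),
        "gauss3": list(
            (config.gauss3.n, config.gauss3.center, config.gauss3.sigma)
        ),
    }
    simple: Dict[str, float] = {}
    pulse_index = {"n": 0, "t_plus": 1, "sigma": 2}
    for name, value in values.items():
        if name not in SYSTEM_PARAMS:
            raise ValueError(f"unknown system parameter {name!r}")
        if name[-1] in "123" and name[:-1] in ("n", "sigma") or name in (
            "t1_plus", "t2_plus", "t3_plus",
        ):
            if name.endswith("_plus"):
                which, idx = f"gauss{name[1]}", 1
            else:
                which, idx = f"gauss{name[-1]}", pulse_index[name[:-1]]
            pulses[which][idx] = value
        else:
            simple[name] = value
    return config.with_overrides(
        gauss1=GaussianPulse(*pulses["gauss1"]),
        gauss2=GaussianPulse(*pulses["gauss2"]),
        gauss3=GaussianPulse(*pulses["gauss3"]),
        **simple,
    )


def fit_system(
    series: KineticsSeries,
    spec: FitSpec,
    base_config: Optional[SystemModelConfig] = None,
) -> FitResult:
    """Global fit of the stock-and-flow model by differential evolution.

    ``base_config`` (default: the bundled SGF+pepsin configuration)
    provides every parameter not listed in ``spec.fixed``/``spec.free``.
    Bounds are required for every free parameter; the optimizer is seeded
    through ``spec.seed`` and therefore fully reproducible. Residuals are
    on absolute area, with the simulated trajectory sampled onto the data
    grid by nearest-grid-point lookup.
    """
    if spec.model != "system":
        raise ValueError("spec.model must be 'system'")
    if base_config is None:
        from . import presets

        base_config = presets.system_sgf_pepsin()
    config = _apply_system_params(base_config, spec.fixed)
    t_max = float(series.times.max())
    if config.t_end < t_max:
        config = config.with_overrides(t_end=t_max)

    free = list(spec.free or ())
    for name in free:
        if name not in SYSTEM_PARAMS:
            raise ValueError(f"unknown system parameter {name!r}")
        if spec.bounds is None or name not in spec.bounds:
            raise ValueError(f"free system parameter {name!r} requires bounds")

    idx = np.clip(
        np.rint(series.times / config.dt).astype(int),
        0,
        int(round(config.t_end / config.dt)),
    )
    obs = series.areas

    def loss_of(cfg: SystemModelConfig) -> Tuple[float, np.ndarray]:
        traj = simulate(cfg)
        pred = traj.areas[idx]
        return float(np.sum((pred - obs) ** 2)), pred

    trace: List[float] = []

    if not free:
        loss, pred = loss_of(config)
        return FitResult(
            estimates=dict(spec.fixed),
            residual_sum=loss,
            r_squared=_safe_r_squared(obs, pred),
            n_points=len(obs),
            converged=True,
            loss_trace=(loss,),
            message="forward run (no free parameters)",
        )

    def objective(theta: np.ndarray) -> float:
        try:
            cfg = _apply_system_params(config, dict(zip(free, theta)))
            loss, _ = loss_of(cfg)
        except (ValueError, RuntimeError):
            loss = 1e30
        trace.append(loss)
        return loss

    opts = spec.options
    result = differential_evolution(
        objective,
        bounds=[tuple(spec.bounds[name]) for name in free],
        seed=spec.seed,
        maxiter=int(opts.get("maxiter", 40)),
        popsize=int(opts.get("popsize", 15)),
        tol=float(opts.get("tol", 0.01)),
        polish=bool(opts.get("polish", True)),
        updating="deferred",
        workers=1,
    )
    estimates = dict(spec.fixed)
    estimates.update({name: float(val) for name, val in zip(free, result.x)})
    final_cfg = _apply_system_params(config, dict(zip(free, result.x)))
    loss, pred = loss_of(final_cfg)
    return FitResult(
        estimates=estimates,
        residual_sum=loss,
        r_squared=_safe_r_squared(obs, pred),
        n_points=len(obs),
        converged=bool(result.success),
        loss_trace=tuple(trace),
        message=str(result.message),
    )
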