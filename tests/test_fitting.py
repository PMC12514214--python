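"""Fitting: least-squares phase fits, the global system fit, and R²."""

from dataclasses import replace

import numpy as np
import pytest

from cmpkinetics import (
    FitSpec,
    KineticsSeries,
    ScenarioSpec,
    fit_phase1,
    fit_phase3,
    fit_system,
    generate,
    r_squared,
    scenario_defaults,
)
from cmpkinetics.fitting import UnderdeterminedError

PEPSIN_PHASE1_TRUTH = {"n1": 0.0116, "t1_plus": 187.5, "n2": 0.015, "sigma2": 35.15}


def phase1_series(noise_cv=0.0, seed=0, duration=600.0):
    from cmpkinetics import presets

    return generate(
        ScenarioSpec(
            scenario="water_ph2",  # closed-form curve, no expansion appended
            ground_truth=presets.phase1_sgf_pepsin(),
            duration=duration,
            noise_cv=noise_cv,
            seed=seed,
            volume_scale_fL=200.0,
            expansion=None,
        )
    )


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == 0.0

    def test_hand_computed_value(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=50)
        pred = obs + rng.normal(scale=0.3, size=50)
        base = r_squared(obs, pred)
        assert r_squared(3.0 * obs + 7.0, 3.0 * pred + 7.0) == pytest.approx(
            base, rel=1e-12
        )

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitPhase1:
    spec = FitSpec(model="phase1", fixed={"sigma1": 11.0, "t2_plus": 300.0})

    def test_noiseless_parameter_recovery(self):
        result = fit_phase1(phase1_series(), self.spec)
        assert result.converged
        for name, truth in PEPSIN_PHASE1_TRUTH.items():
            assert result.estimates[name] == pytest.approx(truth, rel=1e-3)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_median_error(self):
        """Median relative error of each free parameter stays below 5% over
        20 seeded replicates at 1% multiplicative noise, 2 fps."""
        errors = {name: [] for name in PEPSIN_PHASE1_TRUTH}
        for seed in range(20):
            result = fit_phase1(phase1_series(noise_cv=0.01, seed=seed), self.spec)
            for name, truth in PEPSIN_PHASE1_TRUTH.items():
                errors[name].append(abs(result.estimates[name] - truth) / truth)
        for name, errs in errors.items():
            assert np.median(errs) < 0.05, name

    def test_constant_series_gives_zero_amplitudes(self):
        series = KineticsSeries(
            times=np.arange(0.0, 600.0, 0.5),
            areas=np.full(1200, 40.0),
            provenance="synthetic",
        )
        result = fit_phase1(series, self.spec)
        assert result.estimates["n1"] == pytest.approx(0.0, abs=1e-6)
        assert result.estimates["n2"] == pytest.approx(0.0, abs=1e-6)

    def test_automatic_t2_from_series_minimum(self):
        # leave t2_plus unset: it defaults to the argmin of the 5-point
        # moving average, a reproducible surrogate for reading the
        # shrinkage minimum off the plot
        times = np.arange(0.0, 600.5, 0.5)
        areas = 40.0 + ((times - 300.0) / 50.0) ** 2
        series = KineticsSeries(times=times, areas=areas, provenance="synthetic")
        result = fit_phase1(series, FitSpec(model="phase1", fixed={"sigma1": 11.0}))
        assert result.estimates["t2_plus"] == pytest.approx(300.0, abs=1.0)

    def test_windowed_fit_on_relative_volume(self):
        # normalizing to the window start must not change the pulse shapes
        result = fit_phase1(
            phase1_series(), replace(self.spec, window=(120.0, 600.0))
        )
        for name, truth in PEPSIN_PHASE1_TRUTH.items():
            assert result.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_underdetermined(self):
        series = KineticsSeries(
            times=np.array([0.0, 1.0, 2.0]),
            areas=np.array([40.0, 39.0, 38.0]),
            provenance="synthetic",
        )
        with pytest.raises(UnderdeterminedError):
            fit_phase1(series, self.spec)

    def test_fixing_at_truth_never_beats_free_fit(self):
        """Nested-model property: the optimum with a parameter fixed at its
        generating value cannot beat the optimum with it free."""
        series = phase1_series(noise_cv=0.01, seed=3)
        free_fit = fit_phase1(series, self.spec)
        fixed_fit = fit_phase1(
            series,
            FitSpec(
                model="phase1",
                free=("v0", "t1_plus", "n2", "sigma2"),
                fixed={"sigma1": 11.0, "t2_plus": 300.0, "n1": 0.0116},
            ),
        )
        assert free_fit.residual_sum <= fixed_fit.residual_sum * (1 + 1e-8)


class TestFitPhase3:
    def test_noiseless_parameter_recovery(self):
        series = generate(
            replace(scenario_defaults("preacidified_pepsin"), noise_cv=0.0)
        )
        result = fit_phase3(series, FitSpec(model="phase3"))
        truth = {
            "v0": 197.4,
            "n3": 0.0141,
            "t3_plus": 193.5,
            "v4": 122.3,
            "t4": 141.7,
            "v_inf": 55.5,
        }
        for name, value in truth.items():
            assert result.estimates[name] == pytest.approx(value, rel=1e-3), name
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_recovered_rate_rounds_to_reference(self):
        series = generate(
            replace(scenario_defaults("preacidified_pepsin"), noise_cv=0.0)
        )
        result = fit_phase3(series, FitSpec(model="phase3"))
        assert float(f"{1.0 / result.estimates['t4']:.1g}") == pytest.approx(7e-3)

    def test_noisy_exponential_branch_recovery(self):
        errs = {"t4": [], "v_inf": [], "v4": []}
        for seed in range(20):
            series = generate(
                replace(scenario_defaults("preacidified_pepsin"), seed=seed)
            )
            result = fit_phase3(series, FitSpec(model="phase3"))
            errs["t4"].append(abs(result.estimates["t4"] - 141.7) / 141.7)
            errs["v_inf"].append(abs(result.estimates["v_inf"] - 55.5) / 55.5)
            errs["v4"].append(abs(result.estimates["v4"] - 122.3) / 122.3)
        for name, values in errs.items():
            assert np.median(values) < 0.05, name

    def test_constant_exponential_branch(self):
        series = KineticsSeries(
            times=np.arange(0.0, 600.0, 0.5),
            areas=np.full(1200, 40.0),
            provenance="synthetic",
        )
        result = fit_phase3(series, FitSpec(model="phase3"))
        volume_pl = 40.0 ** 1.5 * 4.0 / (3.0 * np.sqrt(np.pi)) / 1000.0
        assert result.estimates["v4"] == pytest.approx(0.0, abs=1e-6)
        assert result.estimates["v_inf"] == pytest.approx(volume_pl, rel=1e-6)

    def test_discontinuity_reported(self):
        series = generate(
            replace(scenario_defaults("preacidified_pepsin"), noise_cv=0.0)
        )
        result = fit_phase3(series, FitSpec(model="phase3"))
        # the two branches are fitted independently; the model's jump at
        # the breakpoint is reported as-is
        assert result.discontinuity == pytest.approx(232.3, abs=1.0)

    def test_underdetermined_branch(self):
        series = KineticsSeries(
            times=np.array([0.0, 200.0, 300.0, 400.0]),
            areas=np.array([40.0, 39.0, 38.0, 37.0]),
            provenance="synthetic",
        )
        with pytest.raises(UnderdeterminedError):
            fit_phase3(series, FitSpec(model="phase3"))


@pytest.fixture(scope="module")
def noiseless_series():
    return generate(
        replace(scenario_defaults("sgf_pepsin"), noise_cv=0.0, duration=1800.0)
    )


class TestFitSystem:
    spec = FitSpec(
        model="system",
        free=("rc2", "rc3"),
        bounds={"rc2": (5e-4, 0.05), "rc3": (0.01, 1.0)},
        seed=7,
    )

    def test_recovers_rate_coefficients(self, noiseless_series):
        result = fit_system(noiseless_series, self.spec)
        assert result.estimates["rc2"] == pytest.approx(0.005, rel=0.01)
        assert result.estimates["rc3"] == pytest.approx(0.1533, rel=0.01)

    def test_seeded_runs_are_bit_identical(self, noiseless_series):
        short = replace(self.spec, options={"maxiter": 5, "polish": False})
        a = fit_system(noiseless_series, short)
        b = fit_system(noiseless_series, short)
        assert a.loss_trace == b.loss_trace
        assert a.estimates == b.estimates

    def test_all_fixed_returns_forward_residual(self, noiseless_series):
        result = fit_system(noiseless_series, FitSpec(model="system", free=()))
        assert result.converged
        assert result.residual_sum == pytest.approx(0.0, abs=1e-12)
        assert result.r_squared == pytest.approx(1.0)

    def test_missing_bounds_rejected(self, noiseless_series):
        with pytest.raises(ValueError, match="bounds"):
            fit_system(
                noiseless_series, FitSpec(model="system", free=("rc2",), seed=1)
            )


class TestFitSpecValidation:
    def test_free_fixed_overlap_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(model="phase1", free=("n1",), fixed={"n1": 0.01})

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(model="phase7")
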