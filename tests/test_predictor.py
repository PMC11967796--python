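"""Resistance-factor law: fitting, prediction, and train/validate evaluation."""

import math

import numpy as np
import pytest

from spindrop import (
    DEFAULT_TRUTH,
    DropletObservation,
    EmulsificationCondition,
    ExpLaw,
    FitError,
    GridSpec,
    NoFlowError,
    OutsideModelRangeError,
    ParameterError,
    PredictiveModel,
    RotorConfig,
    SyntheticTruth,
    UntrainedAccelerationError,
    evaluate_model,
    fit_exp_law,
    generate_condition_grid,
    generate_observations,
    predict_diameter,
    predict_frequency,
    resistance_factor,
    true_diameter,
)
from spindrop import io, units


@pytest.fixture
def condition_case(square20, hydrophobic_fluids, rotor_case):
    return EmulsificationCondition(square20, hydrophobic_fluids, rotor_case)


@pytest.fixture
def noiseless_truth():
    return SyntheticTruth(diameter_cv_pct=0.0, condition_scatter_pct=0.0)


@pytest.fixture
def grid():
    return generate_condition_grid()


@pytest.fixture
def noiseless_observations(grid, noiseless_truth):
    return generate_observations(grid, noiseless_truth, seed=0)


class TestResistanceFactor:
    def test_zero_at_hydraulic_diameter(self, condition_case):
        d0 = condition_case.diameter_floor
        assert resistance_factor(condition_case, d0) == pytest.approx(0.0, abs=1e-6)

    def test_hand_evaluation(self, square20, hydrophobic_fluids):
        # Construct a condition whose V_in is exactly 0.05 m/s by inverting
        # the hydraulics for the required driving pressure.
        target_v = 0.05
        state_probe = EmulsificationCondition(square20, hydrophobic_fluids,
                                              RotorConfig(523.599, 0.018, 0.006)).state
        needed = target_v * state_probe.hydraulic_resistance * square20.cross_section
        p_aqu = needed - state_probe.capillary_pressure
        omega = math.sqrt(2 * p_aqu / (1000.0 * (0.024**2 - 0.018**2)))
        condition = EmulsificationCondition(square20, hydrophobic_fluids,
                                            RotorConfig(omega, 0.018, 0.006))
        assert condition.v_in == pytest.approx(0.05, rel=1e-12)
        assert resistance_factor(condition, 150e-6) == pytest.approx(1.733e4, rel=1e-3)

    def test_strictly_increasing_in_diameter(self, condition_case):
        ds = np.linspace(60e-6, 400e-6, 20)
        rf = [resistance_factor(condition_case, d) for d in ds]
        assert all(b > a for a, b in zip(rf, rf[1:]))

    def test_no_flow_rejected(self, square20, hydrophobic_fluids):
        stalled = EmulsificationCondition(square20, hydrophobic_fluids,
                                          RotorConfig(10.0, 0.018, 0.006))
        with pytest.raises(NoFlowError):
            resistance_factor(stalled, 150e-6)


class TestFitExpLaw:
    def test_exact_recovery_on_noiseless_data(self, noiseless_observations, noiseless_truth):
        group = [o for o in noiseless_observations
                 if abs(o.condition.acceleration - 3600.0) < 36.0]
        law = fit_exp_law(group)
        assert law.alpha == pytest.approx(noiseless_truth.alpha(3600.0), rel=1e-8)
        assert law.beta == pytest.approx(noiseless_truth.beta(3600.0), rel=1e-8)

    def test_channels_collapse_onto_one_line(self, noiseless_observations):
        """Conditions with different channel sizes share one law per acceleration."""
        group = [o for o in noiseless_observations
                 if abs(o.condition.acceleration - 2500.0) < 25.0]
        widths = {o.condition.channel.width for o in group}
        assert len(widths) == 3
        assert fit_exp_law(group).r_squared > 0.99

    def test_beta_recovered_within_5pct_at_1pct_noise(self, noiseless_truth):
        """20 points at one acceleration, 1% multiplicative diameter noise."""
        spec = GridSpec(accelerations=(3600.0,),
                        r2_mm=(3.0, 3.75, 4.5, 5.25, 6.0, 6.75, 7.5))
        conditions = generate_condition_grid(spec)[:20]
        rng = np.random.default_rng(42)
        observations = []
        for c in conditions:
            d = true_diameter(c, noiseless_truth) * rng.lognormal(0.0, 0.01)
            observations.append(DropletObservation(c, d))
        law = fit_exp_law(observations)
        assert law.beta == pytest.approx(noiseless_truth.beta(3600.0), rel=0.05)

    def test_too_few_points_rejected(self, noiseless_observations):
        with pytest.raises(FitError):
            fit_exp_law(noiseless_observations[:2])

    def test_mixed_accelerations_rejected(self, noiseless_observations):
        with pytest.raises(FitError, match="acceleration group"):
            fit_exp_law(noiseless_observations)


class TestPredictDiameter:
    def test_round_trip_self_consistency(self, grid, noiseless_truth):
        """Diameters generated from a law are recovered by prediction."""
        model = PredictiveModel(
            [noiseless_truth.law(a) for a in (1500.0, 2500.0, 3600.0, 4800.0, 6579.7)]
        )
        checked = 0
        for condition in grid:
            if condition.regime != "periodic_dripping":
                continue
            d_star = true_diameter(condition, noiseless_truth)
            d_pred = predict_diameter(condition, model)
            assert abs(d_pred - d_star) / d_star < 1e-6
            checked += 1
        assert checked >= 50

    def test_agrees_with_grid_scan_oracle(self, grid, noiseless_truth):
        """Brute-force scan over 10^4 diameters agrees within one grid step."""
        model = PredictiveModel([noiseless_truth.law(2500.0)])
        condition = next(c for c in grid if abs(c.acceleration - 2500.0) < 25.0)
        lo = condition.diameter_floor * (1 + 1e-6)
        ds = np.linspace(lo, 1e-3, 10_000)
        law = model.laws[0]
        residual = np.abs(
            np.array([resistance_factor(condition, d) for d in ds]) - law.alpha * np.exp(-law.beta * ds)
        )
        oracle = ds[residual.argmin()]
        solved = predict_diameter(condition, model)
        assert abs(solved - oracle) <= ds[1] - ds[0]

    def test_diameter_increases_with_flow_rate(self, square20, hydrophobic_fluids, noiseless_truth):
        """At fixed acceleration and law, more flow means bigger droplets."""
        a = 3600.0
        model = PredictiveModel([noiseless_truth.law(a)])
        omega = math.sqrt(a / 0.024)
        predictions = []
        for r2_mm in (4.0, 5.0, 6.0, 7.0):  # same a, deeper column -> higher V_in
            rotor = RotorConfig(omega, 0.024 - r2_mm * 1e-3, r2_mm * 1e-3)
            condition = EmulsificationCondition(square20, hydrophobic_fluids, rotor)
            predictions.append((condition.v_in, predict_diameter(condition, model)))
        predictions.sort()
        vs, ds = zip(*predictions)
        assert all(b > a_ for a_, b in zip(ds, ds[1:]))

    def test_prediction_exceeds_hydraulic_diameter(self, grid, noiseless_truth):
        model = PredictiveModel([noiseless_truth.law(1500.0)])
        condition = next(c for c in grid if abs(c.acceleration - 1500.0) < 15.0)
        assert predict_diameter(condition, model) > condition.diameter_floor

    def test_untrained_acceleration_raises(self, condition_case):
        model = PredictiveModel([ExpLaw(1500.0, 1e5, 1e4)])
        with pytest.raises(UntrainedAccelerationError):
            predict_diameter(condition_case, model)

    def test_interpolation_mode_covers_intermediate_acceleration(
        self, square20, hydrophobic_fluids, noiseless_truth
    ):
        model = PredictiveModel([noiseless_truth.law(1500.0), noiseless_truth.law(2500.0)])
        a_mid = 2000.0
        omega = math.sqrt(a_mid / 0.024)
        condition = EmulsificationCondition(square20, hydrophobic_fluids,
                                            RotorConfig(omega, 0.018, 0.006))
        d = predict_diameter(condition, model, interpolate=True)
        # Exact at interior points because the truth family is itself linear
        # in ln(alpha) and beta over acceleration.
        assert d == pytest.approx(true_diameter(condition, noiseless_truth), rel=1e-6)

    def test_no_root_in_bracket_raises(self, condition_case):
        # An implausibly small alpha puts the law below the resistance curve
        # over the whole bracket.
        model = PredictiveModel([ExpLaw(condition_case.acceleration, 1e-6, 1e4)])
        with pytest.raises(OutsideModelRangeError):
            predict_diameter(condition_case, model)


class TestPredictFrequency:
    def test_hand_evaluation(self, square20, hydrophobic_fluids):
        state_probe = EmulsificationCondition(square20, hydrophobic_fluids,
                                              RotorConfig(523.599, 0.018, 0.006)).state
        needed = 0.1 * state_probe.hydraulic_resistance * square20.cross_section
        omega = math.sqrt(2 * (needed - state_probe.capillary_pressure)
                          / (1000.0 * (0.024**2 - 0.018**2)))
        condition = EmulsificationCondition(square20, hydrophobic_fluids,
                                            RotorConfig(omega, 0.018, 0.006))
        assert predict_frequency(condition, 145e-6) == pytest.approx(25.1, rel=5e-3)

    def test_volume_conservation_identity(self, condition_case):
        d = 145e-6
        f = predict_frequency(condition_case, d)
        assert f * math.pi * d**3 / 6 == pytest.approx(
            condition_case.channel.cross_section * condition_case.v_in
        )

    def test_cubic_scaling(self, condition_case):
        assert predict_frequency(condition_case, 72.5e-6) == pytest.approx(
            8 * predict_frequency(condition_case, 145e-6)
        )


class TestEvaluateModel:
    def test_noiseless_recovery_below_0p1_pct(self, noiseless_observations):
        result = evaluate_model(noiseless_observations, seed=0)
        assert result.mean_abs_rel_error_pct < 0.1

    def test_noisy_dataset_error_order_of_percent(self, grid):
        observations = generate_observations(grid, DEFAULT_TRUTH, seed=1)
        result = evaluate_model(observations, seed=2)
        assert 0.1 < result.mean_abs_rel_error_pct < 5.0

    def test_split_proportions(self, noiseless_observations):
        result = evaluate_model(noiseless_observations, seed=0)
        total = result.n_train + result.n_validation
        assert total == len(noiseless_observations)
        assert result.n_train / total == pytest.approx(2 / 3, abs=0.05)

    def test_deficient_stratum_listed(self, noiseless_observations):
        slim = [o for o in noiseless_observations
                if abs(o.condition.acceleration - 1500.0) < 15.0][:3]
        more = [o for o in noiseless_observations
                if abs(o.condition.acceleration - 2500.0) < 25.0]
        with pytest.raises(FitError, match="fewer than 3"):
            evaluate_model(slim + more, seed=0)

    def test_unit_ingest_invariance(self, tmp_path, noiseless_observations):
        """Writing to lab-unit CSV and reading back gives identical errors."""
        path = tmp_path / "obs.csv"
        io.write_observations(noiseless_observations, path)
        round_tripped = io.read_observations(path)
        a = evaluate_model(noiseless_observations, seed=7).mean_abs_rel_error_pct
        b = evaluate_model(round_tripped, seed=7).mean_abs_rel_error_pct
        assert a == pytest.approx(b, rel=1e-6)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, noiseless_observations):
        model = PredictiveModel.fit(noiseless_observations)
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = PredictiveModel.from_json(path)
        assert [l.acceleration for l in restored.laws] == [l.acceleration for l in model.laws]
        for a, b in zip(model.laws, restored.laws):
            assert b.alpha == pytest.approx(a.alpha)
            assert b.beta == pytest.approx(a.beta)

    def test_laws_must_be_distinct(self):
        with pytest.raises(ParameterError):
            PredictiveModel([ExpLaw(1500.0, 1e5, 1e4), ExpLaw(1501.0, 1e5, 1e4)])
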