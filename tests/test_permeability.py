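"""Permeability fitting: objective, window, recovery, reliability, groups."""

import numpy as np
import pytest

from crcscaffold import (
    FiltrationTrace,
    apply_window,
    column_height,
    compare_permeability_groups,
    fit_permeability,
    objective_I,
    reliability_summary,
)
from crcscaffold.errors import InsufficientGroupError, InsufficientRepeatsError, NoUsablePointsError
from crcscaffold.permeability import PermeabilityEstimate, estimates_to_frame
from crcscaffold.simulate import gen_filtration_trace, gen_group_permeabilities, gen_reliability_traces


def exact_trace(k, geom, fluid, n=50, t_end=None):
    from crcscaffold import time_to_height

    t_end = t_end or time_to_height(100.0, k, geom, fluid)
    times = np.linspace(0.0, t_end, n)
    return FiltrationTrace("S", "fresh", times, column_height(times, 0.0, k, geom, fluid))


class TestObjective:
    def test_zero_at_true_permeability(self, geom, fluid):
        trace = exact_trace(500.0, geom, fluid)
        assert objective_I(trace, 500.0, geom, fluid) == pytest.approx(0.0, abs=1e-20)

    def test_positive_away_from_truth(self, geom, fluid):
        trace = exact_trace(500.0, geom, fluid)
        assert objective_I(trace, 800.0, geom, fluid) > 0

    def test_three_point_hand_computation(self, geom, fluid):
        # model heights at K=400: H(t) = 210 exp(-rate t), rate = 400*0.25*9.81e-6/2
        rate = 400.0 * 0.25 * 9.81e-6 / 2.0
        times = np.array([0.0, 500.0, 1500.0])
        observed = np.array([210.0, 160.0, 110.0])
        model = 210.0 * np.exp(-rate * times)
        expected = np.mean((1.0 - model / observed) ** 2)
        trace = FiltrationTrace("toy", "fresh", times, observed)
        assert objective_I(trace, 400.0, geom, fluid) == pytest.approx(expected, rel=1e-12)

    def test_empty_window_raises(self, geom, fluid):
        trace = FiltrationTrace("low", "fresh", [0.0, 1.0, 2.0], [50.0, 40.0, 30.0])
        with pytest.raises(NoUsablePointsError):
            objective_I(trace, 100.0, geom, fluid)


class TestApplyWindow:
    def test_all_in_window_is_identity(self, geom, fluid):
        trace = exact_trace(500.0, geom, fluid)
        out = apply_window(trace, geom)
        assert np.array_equal(out.heights_mm, trace.heights_mm)

    def test_matches_brute_force_filter(self, geom):
        times = np.arange(9, dtype=float)
        heights = np.array([250.0, 230.0, 210.0, 180.0, 150.0, 120.0, 100.0, 80.0, 50.0])
        trace = FiltrationTrace("span", "fresh", times, heights)
        out = apply_window(trace, geom)
        keep = [(t, h) for t, h in zip(times, heights) if 100.0 <= h <= 210.0]
        assert len(out) == len(keep)
        assert np.array_equal(out.heights_mm, [h for _, h in keep])
        assert np.array_equal(out.times_s, [t for t, _ in keep])

    def test_boundaries_are_closed(self, geom):
        trace = FiltrationTrace("edge", "fresh", [0.0, 1.0, 2.0], [210.0, 150.0, 100.0])
        assert len(apply_window(trace, geom)) == 3


class TestFitPermeability:
    def test_noiseless_recovery_to_machine_tolerance(self, geom, fluid):
        est = fit_permeability(exact_trace(500.0, geom, fluid), geom, fluid)
        assert est.k_mm4_per_Ns == pytest.approx(500.0, rel=1e-6)
        assert est.converged

    def test_noisy_recovery_within_five_percent_and_matches_grid_oracle(self, geom, fluid):
        trace = gen_filtration_trace(500.0, geom, fluid, n_points=50, noise_sd_rel=0.01, seed=77)
        est = fit_permeability(trace, geom, fluid)
        assert est.k_mm4_per_Ns == pytest.approx(500.0, rel=0.05)
        # dense grid search confirms the minimiser
        grid = np.linspace(400.0, 600.0, 4001)
        vals = [objective_I(trace, k, geom, fluid) for k in grid]
        k_grid = grid[int(np.argmin(vals))]
        assert est.k_mm4_per_Ns == pytest.approx(k_grid, abs=2 * (grid[1] - grid[0]))
        assert est.objective <= min(vals) + 1e-15

    def test_constant_trace_clamped_to_zero_with_warning(self, geom, fluid):
        trace = FiltrationTrace("flat", "fresh", np.arange(5.0), np.full(5, 150.0))
        with pytest.warns(UserWarning):
            est = fit_permeability(trace, geom, fluid)
        assert est.k_mm4_per_Ns == 0.0
        assert est.converged
        assert est.warning is not None

    def test_too_few_in_window_points_raises(self, geom, fluid):
        trace = FiltrationTrace("thin", "fresh", [0.0, 1.0, 2.0], [210.0, 150.0, 60.0])
        with pytest.raises(NoUsablePointsError):
            fit_permeability(trace, geom, fluid)

    def test_objective_unimodal_over_grid_for_noiseless_trace(self, geom, fluid):
        trace = exact_trace(1000.0, geom, fluid)
        grid = np.linspace(10.0, 4000.0, 400)
        vals = np.array([objective_I(trace, k, geom, fluid) for k in grid])
        sign_changes = np.sum(np.diff(np.sign(np.diff(vals))) != 0)
        assert sign_changes <= 1  # one interior minimum

    def test_time_origin_shift_invariance(self, geom, fluid):
        trace = gen_filtration_trace(800.0, geom, fluid, noise_sd_rel=0.01, seed=5)
        shifted = FiltrationTrace(
            trace.sample_id, trace.group, trace.times_s + 1234.5, trace.heights_mm
        )
        k0 = fit_permeability(trace, geom, fluid).k_mm4_per_Ns
        k1 = fit_permeability(shifted, geom, fluid).k_mm4_per_Ns
        assert k1 == pytest.approx(k0, rel=1e-6)


class TestParameterRecoveryProperty:
    def test_median_error_under_one_percent_noise(self, geom, fluid):
        """200 traces, K log-uniform in [10, 1e4], 1% noise: median error < 2%, p95 < 10%."""
        rng = np.random.default_rng(2024)
        errors = []
        for _ in range(200):
            k_true = 10.0 ** rng.uniform(1, 4)
            trace = gen_filtration_trace(k_true, geom, fluid, noise_sd_rel=0.01, seed=rng)
            est = fit_permeability(trace, geom, fluid)
            errors.append(abs(est.k_mm4_per_Ns / k_true - 1.0))
        assert np.median(errors) < 0.02
        assert np.quantile(errors, 0.95) < 0.10


class TestReliability:
    def test_identical_repeats_have_zero_cv(self):
        ests = [
            PermeabilityEstimate("s1", "reference_material", r, 1000.0, 0.0, 50, True, (100, 210))
            for r in range(5)
        ]
        summary = reliability_summary(ests)
        assert summary.per_sample["cv_k"].iloc[0] == 0.0

    def test_noiseless_protocol_cv_zero(self, geom, fluid):
        traces = gen_reliability_traces(1000.0, n_samples=2, n_repeats=5, noise_sd_rel=0.0, seed=0)
        ests = [fit_permeability(t, geom, fluid) for t in traces]
        summary = reliability_summary(ests)
        assert (summary.per_sample["cv_k"] < 1e-6).all()
        assert summary.n_samples == 2

    def test_singleton_repeat_raises(self):
        ests = [PermeabilityEstimate("s1", "reference_material", 0, 1000.0, 0.0, 50, True, (100, 210))]
        with pytest.raises(InsufficientRepeatsError):
            reliability_summary(ests)


class TestGroupComparison:
    def _estimates(self, values_by_group):
        out = []
        for group, values in values_by_group.items():
            for i, v in enumerate(values):
                out.append(
                    PermeabilityEstimate(f"{group}_{i}", group, 0, v, 0.0, 50, True, (100, 210))
                )
        return out

    def test_identical_groups_not_significant(self):
        vals = [100.0, 120.0, 140.0, 160.0, 180.0]
        table = compare_permeability_groups(
            self._estimates({"fresh": vals, "decellularized": vals})
        )
        assert (table["p_value"] > 0.05).all()
        assert (table["stars"] == "ns").all()

    def test_separated_groups_flagged_significant(self, geom, fluid):
        traces, _ = gen_group_permeabilities(seed=11, n_per_group=8)
        ests = [fit_permeability(t, geom, fluid) for t in traces]
        table = compare_permeability_groups(ests)
        row = table[(table["group_a"] == "decellularized") & (table["group_b"] == "fresh")]
        assert row["p_value"].iloc[0] < 0.05
        assert row["median_a"].iloc[0] > row["median_b"].iloc[0]

    def test_undersized_group_raises(self):
        with pytest.raises(InsufficientGroupError):
            compare_permeability_groups(
                self._estimates({"fresh": [1.0, 2.0], "decellularized": [5.0, 6.0, 7.0]})
            )

    def test_repeats_averaged_per_sample(self):
        ests = self._estimates({"fresh": [100.0] * 3, "decellularized": [500.0] * 3})
        frame = estimates_to_frame(ests)
        assert len(frame) == 6
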