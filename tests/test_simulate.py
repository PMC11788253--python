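"""Delivery simulation, commissioning helpers and the exact delta-t solver."""

import numpy as np
import pytest

from trfd import (
    DeltaTParams,
    Grid2D,
    MachineModel,
    SpotList,
    commission_dose_per_mu,
    delta_t_map,
    field_to_spot_ratio,
    fit_spot_sigma,
    scale_time,
    scenario_qa_grid,
    sim_delta_t,
    simulate_delivery,
)
from conftest import gaussian_map


def brute_force_ratio(pattern: SpotList, sigma: float) -> float:
    """Independent superposition sum at the pattern center."""
    cx, cy = pattern.x_mm.mean(), pattern.y_mm.mean()
    total = 0.0
    for x, y, _ in pattern:
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        total += np.exp(-d2 / (2 * sigma**2))
    return total


class TestSimulateDelivery:
    def test_single_spot_peak_dose(self, machine):
        # dose_per_mu(120 nA) = 0.05 Gy/MU exactly on the default line
        spots = SpotList([0.0], [0.0], [100.0])
        sim = simulate_delivery(spots, machine, 120.0,
                                grid=Grid2D.centered(12.0, 0.1))
        dose = sim.final_dose_map()
        assert machine.dose_per_mu(120.0) == pytest.approx(0.05)
        # nearest pixel center is 0.05 mm off-axis on the even-sized grid
        assert dose.values.max() == pytest.approx(5.0, rel=1e-3)

    def test_beam_time_additivity(self):
        spots = SpotList([0, 5, 10], [0, 0, 0], [50, 50, 50])
        m0 = MachineModel(time_per_mu=1e-3, transition_time_s=0.0)
        m2 = MachineModel(time_per_mu=1e-3, transition_time_s=2e-3)
        assert simulate_delivery(spots, m0, 120.0).total_time_s == pytest.approx(0.15)
        assert simulate_delivery(spots, m2, 120.0).total_time_s == pytest.approx(0.154)

    def test_grid_too_small_rejected(self, machine):
        spots = SpotList([30.0], [0.0], [100.0])
        with pytest.raises(ValueError, match="grid too small"):
            simulate_delivery(spots, machine, 120.0, grid=Grid2D.centered(10.0, 0.5))

    def test_short_spot_warns(self, machine):
        spots = SpotList([0.0], [0.0], [1.0])  # 1 ms < 3 ms minimum
        with pytest.warns(UserWarning, match="minimum spot duration"):
            simulate_delivery(spots, machine, 120.0, grid=Grid2D.centered(12.0, 0.5))

    def test_dose_conservation_gaussian_integral(self, machine):
        spots = SpotList([0.0], [0.0], [100.0])
        sim = simulate_delivery(spots, machine, 120.0,
                                grid=Grid2D.centered(19.0, 0.1))
        dose = sim.final_dose_map()
        integral = dose.values.sum() * 0.1**2
        expected = 2 * np.pi * machine.spot_sigma_mm**2 * 5.0
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_qa_grid_central_dose(self, machine):
        # scenario MU choice must reproduce the requested central-axis dose
        plan = scenario_qa_grid(total_dose_gy=15.0, current_nA=120.0, machine=machine)
        sim = simulate_delivery(plan, machine, 120.0, grid=Grid2D.centered(25.0, 0.2))
        center = sim.accumulation_at([0.0], [0.0], [sim.total_time_s + 1.0])[0, 0]
        assert center == pytest.approx(15.0, rel=1e-6)


class TestScaleTime:
    def test_doubling_scales_every_delta_t(self, machine):
        spots = SpotList([-4, 0, 4], [0, 0, 0], [80, 80, 80])
        sim = simulate_delivery(spots, machine, 120.0, grid=Grid2D.centered(16.0, 1.0))
        scaled = scale_time(sim, 2.0 * sim.total_time_s)
        a = sim_delta_t(sim)
        b = sim_delta_t(scaled)
        assert np.allclose(b.delta_t[b.mask], 2.0 * a.delta_t[a.mask], rtol=1e-12)
        assert np.allclose(
            scaled.final_dose_map().values, sim.final_dose_map().values
        )

    def test_identity_and_errors(self, machine):
        spots = SpotList([0.0], [0.0], [100.0])
        sim = simulate_delivery(spots, machine, 120.0, grid=Grid2D.centered(12.0, 1.0))
        same = scale_time(sim, sim.total_time_s)
        assert np.allclose(same.events, sim.events)
        with pytest.raises(ValueError):
            scale_time(sim, 0.0)


class TestSimDeltaT:
    def test_single_spot_uniform_ramp(self, machine):
        spots = SpotList([0.0], [0.0], [93.0])  # 0.093 s delivery
        sim = simulate_delivery(spots, machine, 120.0, grid=Grid2D.centered(10.0, 0.5))
        dtm = sim_delta_t(sim)
        assert np.allclose(dtm.delta_t[dtm.mask], 0.8 * 0.093, rtol=1e-12)

    def test_two_distant_spots_no_crosstalk(self, machine):
        # 20 sigma apart: each sub-field behaves like its own single spot
        d = 20 * machine.spot_sigma_mm
        spots = SpotList([-d / 2, d / 2], [0.0, 0.0], [100.0, 100.0])
        sim = simulate_delivery(spots, machine, 120.0,
                                grid=Grid2D.centered(d / 2 + 12.0, 1.0))
        dtm = sim_delta_t(sim)
        xx, _ = np.meshgrid(sim.grid.x_centers(), sim.grid.y_centers())
        near = np.abs(np.abs(xx) - d / 2) < 2 * machine.spot_sigma_mm
        assert np.allclose(dtm.delta_t[near], 0.8 * 0.1, atol=1e-4)

    def test_matches_brute_force_curve_oracle(self, machine):
        rng = np.random.default_rng(42)
        params = DeltaTParams()
        for _ in range(10):
            n = rng.integers(2, 10)
            spots = SpotList(
                rng.uniform(-8, 8, n), rng.uniform(-8, 8, n), rng.uniform(30, 150, n)
            )
            sim = simulate_delivery(spots, machine, 120.0,
                                    grid=Grid2D.centered(11.0, 2.0))
            dtm = sim_delta_t(sim, params)
            # independent oracle: sample every pixel's curve at 10 kHz and run
            # the measurement-side normalization + crossing search
            times = sim.sample_times(tail_s=1.5)
            xx, yy = np.meshgrid(sim.grid.x_centers(), sim.grid.y_centers())
            curves = sim.accumulation_at(xx.ravel(), yy.ravel(), times)
            stack = curves.T.reshape(times.size, *sim.grid.shape)
            oracle = delta_t_map(stack, sim.sample_rate_hz, params)
            both = dtm.mask & oracle.mask
            assert both.all()
            assert np.max(np.abs(dtm.delta_t[both] - oracle.delta_t[both])) < 2e-4

    def test_midpoint_pixel_spans_both_deliveries(self, machine):
        spots = SpotList([-3.0, 3.0], [0.0, 0.0], [100.0, 100.0])
        m = MachineModel(transition_time_s=0.05)
        sim = simulate_delivery(spots, m, 120.0, grid=Grid2D.centered(12.0, 0.5))
        dtm = sim_delta_t(sim)
        mid = sim.accumulation_at([0.0], [0.0], sim.sample_times(1.5))
        stack = mid.T.reshape(-1, 1, 1)
        oracle = delta_t_map(stack, sim.sample_rate_hz)
        j = np.argmin(np.abs(sim.grid.x_centers()))
        i = np.argmin(np.abs(sim.grid.y_centers()))
        assert dtm.delta_t[i, j] == pytest.approx(oracle.delta_t[0, 0], abs=2e-4)
        # the midpoint delta-t spans both ramps plus the transition gap
        assert dtm.delta_t[i, j] > 0.1 + 0.05


class TestSpotSigmaFit:
    def test_reference_sigma_recovered(self):
        m = gaussian_map(sigma_mm=3.8, pitch=0.14, half_mm=15.0)
        fit = fit_spot_sigma(m)
        assert fit.sigma_mm == pytest.approx(3.8, rel=0.005)

    def test_anisotropic_mean_convention(self):
        g = Grid2D.centered(15.0, 0.14)
        xx, yy = np.meshgrid(g.x_centers(), g.y_centers())
        from trfd import ScalarMap

        vals = 4.0 * np.exp(-(xx**2 / (2 * 3.6**2) + yy**2 / (2 * 4.0**2)))
        fit = fit_spot_sigma(ScalarMap(vals, 0.14, g.origin_mm))
        assert fit.sigma_mm == pytest.approx(3.8, rel=1e-3)
        assert fit.sigma_x_mm == pytest.approx(3.6, rel=1e-3)
        assert fit.sigma_y_mm == pytest.approx(4.0, rel=1e-3)

    def test_flat_map_rejected(self):
        from trfd import ScalarMap

        with pytest.raises(ValueError):
            fit_spot_sigma(ScalarMap(np.zeros((50, 50)), 0.5, (0, 0)))


class TestFieldToSpotRatio:
    def test_single_spot_is_one(self):
        assert field_to_spot_ratio(SpotList([0.0], [0.0], [1.0]), 3.8) == 1.0

    def test_qa_grid_matches_brute_force(self, machine):
        plan = scenario_qa_grid(machine=machine)
        ratio = field_to_spot_ratio(plan, 3.8)
        assert ratio == pytest.approx(brute_force_ratio(plan, 3.8), rel=1e-12)
        assert ratio == pytest.approx(3.629, abs=1e-3)

    def test_monotone_in_sigma(self, machine):
        plan = scenario_qa_grid(machine=machine)
        ratios = [field_to_spot_ratio(plan, s) for s in (2.0, 3.0, 3.8, 5.0)]
        assert np.all(np.diff(ratios) > 0)

    def test_nonuniform_pattern_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            field_to_spot_ratio(SpotList([0, 5], [0, 0], [1.0, 2.0]), 3.8)


class TestCommissioning:
    def test_two_point_line(self):
        pattern = SpotList([0.0], [0.0], [1.0])
        meas = [(25.0, 0.04 * 10, pattern, 10.0), (215.0, 0.06 * 10, pattern, 10.0)]
        intercept, slope = commission_dose_per_mu(meas, 3.8)
        assert slope == pytest.approx((0.06 - 0.04) / 190.0)
        assert intercept + 25.0 * slope == pytest.approx(0.04)

    def test_four_current_self_consistency(self, machine):
        plan = scenario_qa_grid(machine=machine)
        ratio = field_to_spot_ratio(plan, machine.spot_sigma_mm)
        meas = []
        for current in (25.0, 60.0, 120.0, 215.0):
            dpm = machine.dose_per_mu(current)
            mu = 100.0
            meas.append((current, dpm * mu * ratio, plan, mu))
        intercept, slope = commission_dose_per_mu(meas, machine.spot_sigma_mm)
        assert intercept == pytest.approx(machine.dose_per_mu_intercept, abs=1e-9)
        assert slope == pytest.approx(machine.dose_per_mu_slope, abs=1e-12)

    def test_single_current_rejected(self):
        pattern = SpotList([0.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="distinct"):
            commission_dose_per_mu([(25.0, 1.0, pattern, 10.0)], 3.8)
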