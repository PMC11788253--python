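"""Delta-t extraction, PBS dose rate, in-field mask and statistics."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from trfd import (
    DeltaTMap,
    DeltaTParams,
    delta_t_map,
    delta_t_statistics,
    infield_mask,
    normalize_accumulation,
    pbs_dose_rate,
    threshold_crossings,
)
from conftest import gaussian_map


def ramp_curve(t0, width, fps, total_s, plateau=1.0):
    t = np.arange(int(round(total_s * fps))) / fps
    return plateau * np.clip((t - t0) / width, 0.0, 1.0)


class TestNormalization:
    def test_plateau_maps_to_100(self):
        curve = ramp_curve(0.2, 0.1, 240.0, 3.0, plateau=5.0)
        norm, tail = normalize_accumulation(curve, 240.0)
        assert tail == pytest.approx(5.0)
        assert norm[-1] == pytest.approx(100.0)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError, match="never irradiated"):
            normalize_accumulation(np.zeros(1000), 240.0)

    def test_noisy_tail_averaging(self, rng):
        curve = ramp_curve(0.1, 0.1, 240.0, 3.0, plateau=2.0)
        curve[-240:] += rng.normal(0, 0.01, 240)
        norm, tail = normalize_accumulation(curve, 240.0)
        # scale factor 100/tail = 50 within the tail-mean precision
        assert 100.0 / tail == pytest.approx(50.0, abs=0.1)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            normalize_accumulation(np.ones(100), 240.0, tail_window_s=1.0)


class TestCrossings:
    def test_linear_ramp_closed_form(self):
        # ramp 0 -> 100 over 0.1 s: crossings at 10% and 90% of the width
        fps = 10_000.0
        curve = ramp_curve(0.0, 0.1, fps, 1.5) * 100
        t1, t2 = threshold_crossings(curve, fps)
        assert t1 == pytest.approx(0.01, abs=1e-9)
        assert t2 == pytest.approx(0.09, abs=1e-9)

    def test_step_rise_within_one_sample(self):
        fps = 240.0
        t = np.arange(int(3 * fps)) / fps
        curve = np.where(t >= 0.5, 100.0, 0.0)
        t1, t2 = threshold_crossings(curve, fps)
        assert abs(t1 - 0.5) <= 1 / fps and abs(t2 - 0.5) <= 1 / fps
        assert t2 - t1 <= 1 / fps

    def test_two_half_deliveries_piecewise_oracle(self):
        # equal ramps on [0, 0.1] and [0.6, 0.7]: t1 = 0.02, t2 = 0.68
        fps = 10_000.0
        t = np.arange(int(2.0 * fps)) / fps
        curve = 50 * np.clip(t / 0.1, 0, 1) + 50 * np.clip((t - 0.6) / 0.1, 0, 1)
        t1, t2 = threshold_crossings(curve, fps)
        assert t1 == pytest.approx(0.02, abs=1e-6)
        assert t2 == pytest.approx(0.68, abs=1e-6)
        assert t2 - t1 == pytest.approx(0.66, abs=1e-5)

    def test_threshold_never_reached(self):
        with pytest.raises(ValueError, match="never reached"):
            threshold_crossings(np.linspace(0, 50, 500), 240.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        width=st.floats(0.05, 0.5),
        t0=st.floats(0.1, 0.5),
        fps=st.sampled_from([240.0, 1000.0, 10_000.0]),
    )
    def test_ramp_delta_t_analytic_property(self, width, t0, fps):
        """delta-t of a linear ramp of width w is exactly 0.8 w when the
        bracketing samples of both crossings lie inside the ramp."""
        curve = ramp_curve(t0, width, fps, t0 + width + 1.5) * 100
        for level_t in (t0 + 0.1 * width, t0 + 0.9 * width):
            i = int(np.floor(level_t * fps))
            assume(t0 <= i / fps and (i + 1) / fps <= t0 + width)
        t1, t2 = threshold_crossings(curve, fps)
        assert t2 - t1 == pytest.approx(0.8 * width, rel=1e-9)

    def test_scale_invariance(self, rng):
        fps = 240.0
        curve = np.maximum.accumulate(rng.uniform(0, 1, 1000))
        curve[-240:] = curve.max()
        n1, _ = normalize_accumulation(curve, fps)
        n2, _ = normalize_accumulation(7.3 * curve, fps)
        assert threshold_crossings(n1, fps) == threshold_crossings(n2, fps)


class TestDeltaTMap:
    def test_uniform_synchronous_ramp(self):
        fps = 240.0
        curve = ramp_curve(0.1, 0.5, fps, 2.0)
        stack = np.tile(curve[:, None, None], (1, 4, 5))
        dtm = delta_t_map(stack, fps)
        assert dtm.mask.all()
        assert np.allclose(dtm.delta_t, 0.8 * 0.5, atol=1e-3)

    def test_unirradiated_half_masked(self):
        fps = 240.0
        curve = ramp_curve(0.1, 0.5, fps, 2.0)
        stack = np.tile(curve[:, None, None], (1, 4, 4))
        stack[:, :, 2:] = 0.0
        dtm = delta_t_map(stack, fps)
        assert dtm.mask[:, :2].all() and not dtm.mask[:, 2:].any()
        assert np.allclose(dtm.delta_t[:, :2], 0.4, atol=1e-3)

    def test_delta_t_never_exceeds_record(self, rng):
        fps = 240.0
        stack = np.maximum.accumulate(rng.uniform(0, 1, (720, 3, 3)), axis=0)
        dtm = delta_t_map(stack, fps)
        assert np.all(dtm.delta_t[dtm.mask] <= 720 / fps)
        assert np.all(dtm.delta_t[dtm.mask] >= 0)


class TestPbsDoseRate:
    def _dtm(self, dt, shape=(2, 2)):
        full = np.full(shape, dt)
        return DeltaTMap(full, np.zeros(shape), full, np.ones(shape, bool), 1.0, (0, 0))

    def test_fractional_threshold(self):
        from trfd import ScalarMap

        dtm = self._dtm(0.08)
        dose = ScalarMap(np.full((2, 2), 10.0), 1.0, (0, 0))
        rate = pbs_dose_rate(dtm, dose, d=0.10)
        assert np.allclose(rate.values, 100.0)  # (0.8 * 10) / 0.08

    def test_relative_mode(self):
        rate = pbs_dose_rate(self._dtm(0.4), d=0.10)
        assert np.allclose(rate.values, 200.0)  # 80% / 0.4 s

    def test_zero_delta_t_masked(self):
        rate = pbs_dose_rate(self._dtm(0.0))
        assert not rate.mask.any()

    def test_absolute_threshold(self):
        from trfd import ScalarMap

        dtm = self._dtm(0.1)
        dose = ScalarMap(np.full((2, 2), 10.0), 1.0, (0, 0))
        rate = pbs_dose_rate(dtm, dose, d=0.5, absolute=True)
        assert np.allclose(rate.values, (10.0 - 1.0) / 0.1)
        with pytest.raises(ValueError, match="D_max/2"):
            pbs_dose_rate(dtm, dose, d=6.0, absolute=True)


class TestInfieldMask:
    def test_gaussian_half_maximum_radius(self):
        sigma = 3.8
        m = gaussian_map(sigma_mm=sigma, pitch=0.14, half_mm=10.0)
        mask = infield_mask(m)
        xx, yy = np.meshgrid(m.x_centers(), m.y_centers())
        r = np.hypot(xx, yy)
        r_half = sigma * np.sqrt(2 * np.log(2))  # 4.474 mm
        assert r_half == pytest.approx(4.474, abs=1e-3)
        assert np.all(r[mask] <= r_half + 1e-9)
        assert np.all(mask[r <= r_half - 1e-9])

    def test_uniform_map_all_true(self):
        from trfd import ScalarMap

        mask = infield_mask(ScalarMap(np.ones((3, 3)), 1.0, (0, 0)))
        assert mask.all()

    def test_frac_one_keeps_only_maximum(self):
        from trfd import ScalarMap

        vals = np.arange(9.0).reshape(3, 3)
        mask = infield_mask(ScalarMap(vals, 1.0, (0, 0)), frac=1.0)
        assert mask.sum() == 1 and mask[2, 2]


class TestStatistics:
    def test_uniform_map(self):
        shape = (3, 3)
        dtm = DeltaTMap(
            np.full(shape, 0.3), np.zeros(shape), np.full(shape, 0.3),
            np.ones(shape, bool), 1.0, (0, 0),
        )
        stats = delta_t_statistics(dtm)
        assert all(v == pytest.approx(0.3) for v in stats.values())

    def test_percentile_linear_interpolation(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        dtm = DeltaTMap(vals, np.zeros_like(vals), vals, np.ones_like(vals, bool),
                        1.0, (0, 0))
        stats = delta_t_statistics(dtm)
        assert stats["p50"] == pytest.approx(50.5)
        assert stats["mean"] == pytest.approx(50.5)
        assert stats["p5"] == pytest.approx(np.percentile(np.arange(1, 101), 5))

    def test_empty_mask_rejected(self):
        dtm = DeltaTMap(np.ones((2, 2)), np.zeros((2, 2)), np.ones((2, 2)),
                        np.zeros((2, 2), bool), 1.0, (0, 0))
        with pytest.raises(ValueError, match="no masked-in"):
            delta_t_statistics(dtm)
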