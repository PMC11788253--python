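"""Self-contained end-to-end study workflows on synthetic footage.

These functions wire the whole toolchain together on forward-modelled
camera recordings: plan -> delivery simulation -> synthetic 8-bit footage
-> measurement chain -> delta-t -> gamma verification.  They are the
package's own validation experiments; real measurements enter the same
:func:`trfd.pipeline.verify` through :func:`trfd.formats.read_frame_stack`.
"""

from __future__ import annotations

import numpy as np

from .delta_t import DeltaTParams
from .densitometry import REFERENCE_CALIBRATION, CalibrationParams
from .footage import FootageConfig, scenario_qa_grid, scenario_revisit, synthesize_footage
from .gamma import GammaCriteria
from .kinetics import REFERENCE_RESPONSE_FUNCTION, ResponseFunction, deconvolve_stack
from .pipeline import VerificationReport, verify
from .simulate import Grid2D, MachineModel, simulate_delivery

__all__ = ["qa_grid_verification", "revisit_plateau"]


def qa_grid_verification(
    seed: int = 17,
    total_dose_gy: float = 15.0,
    current_nA: float = 120.0,
    pixel_pitch_mm: float = 0.35,
    n_pixels: int = 128,
    noise_sigma_pv: float = 1.0,
    machine: MachineModel | None = None,
    cal: CalibrationParams | None = None,
    rf: ResponseFunction | None = None,
    post_roll_s: float = 60.0,
) -> VerificationReport:
    """Verify a uniform QA grid against its own generating plan.

    A 7x7, 5 mm-spacing, snake-ordered spot grid (3 x 3 cm^2 field) is
    simulated, rendered as noisy quantized 240 fps footage on an
    ``n_pixels``-square camera region, pushed through the full measurement
    chain, and compared to the noise-free simulated delta-t map with a local
    gamma evaluation (10% / 2 mm) over the in-field (50% isodose) pixels.
    The camera pitch default (0.35 mm) covers the whole field plus margin on
    a 128x128 region.
    """
    machine = machine or MachineModel()
    cal = cal or REFERENCE_CALIBRATION
    if rf is None:
        rf = REFERENCE_RESPONSE_FUNCTION
    if post_roll_s != rf.duration_s:
        rf = ResponseFunction(
            rf.offset, rf.a_shift, rf.c_slope, duration_s=post_roll_s
        )
    spots = scenario_qa_grid(
        field_mm=30.0,
        spacing_mm=5.0,
        total_dose_gy=total_dose_gy,
        current_nA=current_nA,
        machine=machine,
    )
    grid = Grid2D(pixel_pitch_mm=pixel_pitch_mm, shape=(n_pixels, n_pixels))
    sim = simulate_delivery(spots, machine, current_nA, grid=grid)
    cfg = FootageConfig(
        seed=seed,
        pixel_pitch_mm=pixel_pitch_mm,
        noise_sigma_pv=noise_sigma_pv,
        post_roll_s=post_roll_s,
    )
    stack = synthesize_footage(sim, cal, rf, cfg)
    return verify(
        stack,
        spots,
        machine,
        cal,
        rf,
        nozzle_current_nA=current_nA,
        measured_beam_time_s=sim.total_time_s,
        criteria=GammaCriteria(value_frac=0.10, distance_mm=2.0),
        dt_params=DeltaTParams(),
        seed=seed,
    )


def revisit_plateau(
    n_steps: int = 2,
    seed: int = 17,
    dose_per_target_gy: float = 10.0,
    current_nA: float = 120.0,
    pixel_pitch_mm: float = 0.7,
    n_pixels: int = 64,
    noise_sigma_pv: float = 1.0,
    machine: MachineModel | None = None,
    cal: CalibrationParams | None = None,
    rf: ResponseFunction | None = None,
    post_roll_s: float = 60.0,
) -> dict:
    """Recover the between-installment plateau of a revisited spot.

    Three targets 15 mm apart on the y axis receive 10 Gy each in
    ``n_steps`` equal installments (snake order).  The center target's
    recovered in-field accumulation should plateau at k/n of its final level
    while the beam is away, demonstrating that revisiting spots leaves the
    dose-accumulation measurement unbiased.  Returns the plateau fractions
    sampled mid-pause and their expected k/n levels.
    """
    machine = machine or MachineModel()
    cal = cal or REFERENCE_CALIBRATION
    if rf is None:
        rf = REFERENCE_RESPONSE_FUNCTION
    if post_roll_s != rf.duration_s:
        rf = ResponseFunction(
            rf.offset, rf.a_shift, rf.c_slope, duration_s=post_roll_s
        )
    spots = scenario_revisit(
        n_steps,
        dose_per_target_gy=dose_per_target_gy,
        current_nA=current_nA,
        machine=machine,
    )
    grid = Grid2D(pixel_pitch_mm=pixel_pitch_mm, shape=(n_pixels, n_pixels))
    sim = simulate_delivery(spots, machine, current_nA, grid=grid)
    cfg = FootageConfig(
        seed=seed,
        pixel_pitch_mm=pixel_pitch_mm,
        noise_sigma_pv=noise_sigma_pv,
        post_roll_s=post_roll_s,
    )
    stack = synthesize_footage(sim, cal, rf, cfg)

    # measurement chain up to the accumulation curve, averaged over the
    # center target's in-field region (50% isodose within |y| < 7.5 mm)
    fps = stack.fps
    t_len = stack.n_frames
    pvf = stack.frames.astype(np.float32)
    od = np.log10(np.float32(256.0) / (pvf + 1.0))
    od -= od[0]
    np.clip(od, 0.0, None, out=od)
    dose = cal.a + cal.b * od + cal.c * np.power(od, np.float32(cal.m))
    h, w = stack.shape
    flat = dose.reshape(t_len, h * w).T
    pulse = deconvolve_stack(flat, rf, fps)
    acc = np.cumsum(pulse, axis=1)
    n_tail = int(round(1.0 * fps))
    tail = acc[:, -n_tail:].mean(axis=1)

    yy = np.repeat(stack.origin_mm[1] + (np.arange(h) + 0.5) * stack.pixel_pitch_mm, w)
    near_center = np.abs(yy) < 7.5
    roi = near_center & (tail >= 0.5 * tail[near_center].max())
    curve = acc[roi].mean(axis=0)
    curve_norm = curve / curve[-n_tail:].mean()

    # mid-pause sampling times for the center target (its installments are
    # spots 1, 4, 7, ... in the alternating sweep)
    center_idx = [p * 3 + 1 for p in range(n_steps)]
    ends = sim.events[:, 1]
    starts = sim.events[:, 0]
    plateaus = []
    expected = []
    for k in range(1, n_steps):
        pause_mid = 0.5 * (ends[center_idx[k - 1]] + starts[center_idx[k]])
        frame = int(round((pause_mid + cfg.pre_roll_s) * fps))
        plateaus.append(float(curve_norm[frame]))
        expected.append(k / n_steps)
    return {
        "plateau_fracs": plateaus,
        "expected_fracs": expected,
        "n_roi_pixels": int(roi.sum()),
        "n_steps": n_steps,
        "seed": seed,
    }
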