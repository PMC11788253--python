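"""End-to-end analysis and verification.

``analyze_frame_stack`` is the measurement chain: pixel values -> net OD ->
relative dose (calibration curve) -> deconvolution by the film response
function -> dose accumulation -> per-pixel delta-t and a relative dose map.
It streams the stack in pixel blocks so a full 60 s, 240 fps recording fits
comfortably in memory.

``verify`` is the pre-treatment verification workflow: analyze the
recording, simulate the plan, scale the simulation to the measured beam
time, register the dose maps, compare the delta-t distributions with a
local gamma evaluation and summarize everything in a
:class:`VerificationReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from . import __version__
from .delta_t import (
    DeltaTMap,
    DeltaTParams,
    delta_t_statistics,
    infield_mask,
)
from .densitometry import CalibrationParams, apply_calibration, pv_to_od
from .formats import FrameStack, ScalarMap, SpotList
from .gamma import GammaCriteria, local_gamma, register_maps, shift_map
from .kinetics import ResponseFunction, inverse_filter
from .simulate import DoseTimeSim, MachineModel, scale_time, sim_delta_t

__all__ = ["AnalysisResult", "analyze_frame_stack", "VerificationReport", "verify"]


@dataclass
class AnalysisResult:
    """Measured delta-t map plus the relative (tail) dose map it came from."""

    delta_t_map: DeltaTMap
    dose: ScalarMap


def analyze_frame_stack(
    stack: FrameStack,
    cal: CalibrationParams,
    rf: ResponseFunction,
    params: DeltaTParams | None = None,
    mask_frac: float = 0.05,
    chunk_px: int = 2048,
) -> AnalysisResult:
    """Run the full measurement chain on a recording.

    ``mask_frac`` masks out pixels whose final (tail) dose is below that
    fraction of the map maximum -- unirradiated film where delta-t is
    undefined.  The dose map is on the relative Gy scale of the calibration
    curve; its absolute level is arbitrary (deconvolution scale cancels in
    the tail normalization) but its shape registers against a simulation.
    """
    params = params or DeltaTParams()
    fps = stack.fps
    t_len = stack.n_frames
    h, w = stack.shape
    n_tail = int(round(params.tail_window_s * fps))
    if t_len <= n_tail:
        raise ValueError("recording shorter than the tail averaging window")
    g = inverse_filter(rf, fps, t_len)
    g32 = g.astype(np.float32)

    n_px = h * w
    pv = stack.frames.reshape(t_len, n_px)
    tail_map = np.empty(n_px)
    t1_map = np.empty(n_px)
    t2_map = np.empty(n_px)
    ok = np.zeros(n_px, dtype=bool)
    full = 2.0**8
    for s in range(0, n_px, chunk_px):
        sl = slice(s, min(s + chunk_px, n_px))
        block = pv[:, sl].T.astype(np.float32)  # (P, T)
        od = np.log10(full / (block + 1.0))
        od -= od[:, :1]  # net OD vs first frame
        np.clip(od, 0.0, None, out=od)
        dose = cal.a + cal.b * od + cal.c * np.power(od, np.float32(cal.m))
        pulse = signal.fftconvolve(dose, g32[None, :], axes=1)[:, :t_len]
        acc = np.cumsum(pulse, axis=1, dtype=np.float64)
        tail = acc[:, -n_tail:].mean(axis=1)
        tail_map[sl] = tail
        valid = tail > 0
        env = np.maximum.accumulate(acc, axis=1)
        for frac, out in ((params.lower_frac, t1_map), (params.upper_frac, t2_map)):
            levels = frac * tail
            reached = env >= levels[:, None]
            idx = np.argmax(reached, axis=1)
            found = reached[:, -1]
            idx_c = np.clip(idx, 1, t_len - 1)
            lo = np.take_along_axis(env, (idx_c - 1)[:, None], axis=1)[:, 0]
            hi = np.take_along_axis(env, idx_c[:, None], axis=1)[:, 0]
            denom = hi - lo
            fr = np.where(denom > 0, (levels - lo) / np.where(denom > 0, denom, 1.0), 1.0)
            t = (idx_c - 1 + fr) / fps
            t = np.where(idx == 0, 0.0, t)
            out[sl] = np.where(found, t, np.nan)
            valid &= found
        ok[sl] = valid
    ok &= tail_map > mask_frac * tail_map.max(initial=0.0)
    dt = np.where(ok, t2_map - t1_map, np.nan)
    origin = stack.origin_mm
    dtm = DeltaTMap(
        delta_t=dt.reshape(h, w),
        t1=t1_map.reshape(h, w),
        t2=t2_map.reshape(h, w),
        mask=ok.reshape(h, w),
        pixel_pitch_mm=stack.pixel_pitch_mm,
        origin_mm=origin,
    )
    dose_map = ScalarMap(
        values=tail_map.reshape(h, w),
        pixel_pitch_mm=stack.pixel_pitch_mm,
        origin_mm=origin,
    )
    return AnalysisResult(delta_t_map=dtm, dose=dose_map)


@dataclass
class VerificationReport:
    """Outcome of a measured-vs-simulated delta-t verification."""

    pass_rate: float
    n_evaluated: int
    shift_mm: tuple[float, float]
    stats_measured: dict
    stats_simulated: dict
    stats_ratio: dict
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__

    def to_json(self, indent: int = 1) -> str:
        payload = {
            "pass_rate": self.pass_rate,
            "n_evaluated": self.n_evaluated,
            "shift_mm": list(self.shift_mm),
            "stats_measured": self.stats_measured,
            "stats_simulated": self.stats_simulated,
            "stats_ratio": self.stats_ratio,
            "parameters": self.parameters,
            "seed": self.seed,
            "version": self.version,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "VerificationReport":
        d = json.loads(text)
        return cls(
            pass_rate=d["pass_rate"],
            n_evaluated=d["n_evaluated"],
            shift_mm=tuple(d["shift_mm"]),
            stats_measured=d["stats_measured"],
            stats_simulated=d["stats_simulated"],
            stats_ratio=d["stats_ratio"],
            parameters=d.get("parameters", {}),
            seed=d.get("seed"),
            version=d.get("version", __version__),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())
        return path


def verify(
    stack: FrameStack,
    spots: SpotList,
    machine: MachineModel,
    cal: CalibrationParams,
    rf: ResponseFunction,
    nozzle_current_nA: float,
    measured_beam_time_s: float | None = None,
    criteria: GammaCriteria | None = None,
    dt_params: DeltaTParams | None = None,
    sim_pitch_mm: float = 0.2,
    seed: int | None = None,
) -> VerificationReport:
    """Measured-vs-simulated delta-t verification of one recording.

    The simulation grid matches the camera extent at ``sim_pitch_mm``; the
    simulated delivery is linearly time-scaled to ``measured_beam_time_s``
    (the beam monitor's total delivery time) when given.  The gamma
    evaluation is restricted to the in-field (50% isodose) region of the
    measured dose map after registration.
    """
    from .simulate import Grid2D, simulate_delivery

    criteria = criteria or GammaCriteria()
    dt_params = dt_params or DeltaTParams()

    analysis = analyze_frame_stack(stack, cal, rf, params=dt_params)
    half = max(
        stack.shape[0] * stack.pixel_pitch_mm,
        stack.shape[1] * stack.pixel_pitch_mm,
    ) / 2.0
    grid = Grid2D.centered(half, sim_pitch_mm)
    sim = simulate_delivery(spots, machine, nozzle_current_nA, grid=grid)
    if measured_beam_time_s is not None:
        sim = scale_time(sim, measured_beam_time_s)
    sim_dose = sim.final_dose_map()
    sim_dtm = sim_delta_t(sim, dt_params)

    shift = register_maps(analysis.dose, sim_dose)
    meas_dtm = shift_map(analysis.delta_t_map, *shift)
    meas_dose = shift_map(analysis.dose, *shift)

    field = infield_mask(meas_dose)
    result = local_gamma(meas_dtm, sim_dtm, criteria, mask=field)

    stats_m = delta_t_statistics(meas_dtm, mask=field)
    stats_s = delta_t_statistics(sim_dtm, mask=infield_mask(sim_dose))
    stats_r = {k: stats_m[k] / stats_s[k] if stats_s[k] else float("nan") for k in stats_m}

    return VerificationReport(
        pass_rate=result.pass_rate,
        n_evaluated=result.n_evaluated,
        shift_mm=shift,
        stats_measured=stats_m,
        stats_simulated=stats_s,
        stats_ratio=stats_r,
        parameters={
            "gamma_value_frac": criteria.value_frac,
            "gamma_distance_mm": criteria.distance_mm,
            "lower_frac": dt_params.lower_frac,
            "upper_frac": dt_params.upper_frac,
            "tail_window_s": dt_params.tail_window_s,
            "nozzle_current_nA": nozzle_current_nA,
            "measured_beam_time_s": measured_beam_time_s,
            "sim_pitch_mm": sim_pitch_mm,
            "machine": machine.to_dict(),
            "calibration": cal.to_dict(),
            "response_function": rf.to_dict(),
        },
        seed=seed,
    )
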