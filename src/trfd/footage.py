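"""Forward model of the camera/film instrument, plus validation scenarios.

Turns a simulated delivery into the 8-bit frame stacks a high-speed camera
would record: per camera pixel the delivered dose is binned into frame
intervals, convolved with the (tail-normalized) film response kernel to add
the post-irradiation coloration, mapped back through the inverse of the
OD-to-dose calibration onto optical density, converted to pixel values on
top of the unirradiated-film baseline, and finally degraded by additive
Gaussian noise, rounding and clipping to [0, 255].

The kernel is normalized to its value at the end of the post-roll,
k_hat = k / k(post_roll_s), so the response tail equals the pixel's final
dose -- the same convention the analysis side adopts by normalizing the
accumulation to its final tail window.

Also provides the validation spot patterns: the uniform QA grid
(3 x 3 cm^2, 5 mm spacing), the revisit patterns (three targets 15 mm apart
on the y axis receiving their dose in 1, 2 or 3 installments), and delivery
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .densitometry import CalibrationParams, apply_calibration, invert_calibration, pv_to_od
from .formats import FrameStack, SpotList
from .kinetics import ResponseFunction, eval_kernel
from .simulate import DoseTimeSim, Grid2D, MachineModel, field_to_spot_ratio

__all__ = [
    "FootageConfig",
    "camera_pixel_pitch_mm",
    "synthesize_footage",
    "scenario_qa_grid",
    "scenario_revisit",
    "reorder_spot_list",
    "snake_order",
]

#: camera film-area geometry: 9 x 9 cm^2 imaged onto 640 x 640 pixels
CAMERA_AREA_MM = 90.0
CAMERA_PIXELS = 640


def camera_pixel_pitch_mm(
    area_mm: float = CAMERA_AREA_MM, n_pixels: int = CAMERA_PIXELS
) -> float:
    """Physical pixel pitch of the camera's effective film area [mm/px]."""
    return area_mm / n_pixels


@dataclass
class FootageConfig:
    """Acquisition parameters of the synthetic recording.

    ``pv_baseline`` is the 8-bit pixel value of unirradiated film under the
    box illumination; ``noise_sigma_pv`` the additive Gaussian sensor noise
    (applied before rounding); ``pre_roll_s``/``post_roll_s`` the recording
    margins around beam delivery (the post-roll must cover the kernel
    stabilization window); ``pixel_pitch_mm`` the camera pixel pitch on the
    film.
    """

    pv_baseline: int = 220
    noise_sigma_pv: float = 1.0
    fps: float = 240.0
    pre_roll_s: float = 1.0
    post_roll_s: float = 60.0
    seed: int = 0
    pixel_pitch_mm: float = CAMERA_AREA_MM / CAMERA_PIXELS
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.pv_baseline < 2**self.bit_depth - 1:
            raise ValueError("pv_baseline must lie strictly inside the PV range")
        if not self.fps > 0:
            raise ValueError("fps must be positive")


def synthesize_footage(
    sim: DoseTimeSim,
    cal: CalibrationParams,
    rf: ResponseFunction,
    cfg: FootageConfig | None = None,
    chunk_px: int = 1024,
) -> FrameStack:
    """Render a simulated delivery as an 8-bit camera recording.

    The camera grid covers the simulation grid extent at the camera pixel
    pitch, centered on the same origin.  Per pixel the frame-binned pulse is
    convolved with the tail-normalized kernel, inverted through the
    calibration to net OD, stacked on the baseline OD and quantized.
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or FootageConfig()
    if cfg.post_roll_s < rf.duration_s:
        raise ValueError(
            "post_roll_s must cover the response-kernel duration "
            f"({rf.duration_s} s)"
        )
    fps = cfg.fps
    x_lo, x_hi, y_lo, y_hi = sim.grid.extent()
    # camera grid: sim extent resampled at the camera pitch, same center
    shape = (
        int(np.floor((y_hi - y_lo) / cfg.pixel_pitch_mm)),
        int(np.floor((x_hi - x_lo) / cfg.pixel_pitch_mm)),
    )
    cam = Grid2D(
        pixel_pitch_mm=cfg.pixel_pitch_mm,
        shape=shape,
        origin_mm=(
            (x_lo + x_hi) / 2.0 - shape[1] * cfg.pixel_pitch_mm / 2.0,
            (y_lo + y_hi) / 2.0 - shape[0] * cfg.pixel_pitch_mm / 2.0,
        ),
    )
    h, w = cam.shape
    n_px = h * w
    total_s = cfg.pre_roll_s + sim.total_time_s + cfg.post_roll_s
    n_frames = int(round(total_s * fps))
    # frame f covers recording time [f, f+1)/fps; beam starts at pre_roll_s
    bounds = np.arange(n_frames + 1) / fps - cfg.pre_roll_s
    ramps = sim.ramp_fractions(bounds)  # (E, n_frames + 1)

    # tail-normalized kernel sampled on the frame clock
    k = eval_kernel(rf, np.arange(min(int(np.ceil(rf.duration_s * fps)) + 1, n_frames)) / fps)
    k_hat = k / eval_kernel(rf, cfg.post_roll_s)

    dose_ceiling = apply_calibration(cal.od_max, cal)
    od_base = float(pv_to_od(cfg.pv_baseline, bit_depth=cfg.bit_depth))
    full = float(2**cfg.bit_depth)
    pv_max = 2**cfg.bit_depth - 1

    xx, yy = np.meshgrid(cam.x_centers(), cam.y_centers())
    xf, yf = xx.ravel(), yy.ravel()
    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((n_frames, n_px), dtype=np.uint8)
    for s in range(0, n_px, chunk_px):
        sl = slice(s, min(s + chunk_px, n_px))
        wts = sim.event_weights(xf[sl], yf[sl]).astype(np.float32)  # (E, P)
        acc = wts.T @ ramps.astype(np.float32)  # (P, n_frames + 1)
        if float(acc.max(initial=0.0)) > dose_ceiling:
            raise ValueError(
                "simulated dose exceeds the calibration range "
                f"({dose_ceiling:.3g} Gy)"
            )
        pulse = np.diff(acc, axis=1)  # dose per frame interval
        response = signal.fftconvolve(pulse, k_hat[None, :].astype(np.float32), axes=1)[
            :, :n_frames
        ]
        np.clip(response, 0.0, None, out=response)
        od_net = invert_calibration(response.astype(float), cal)
        pv = full / np.power(10.0, od_base + od_net) - 1.0
        if cfg.noise_sigma_pv > 0:
            pv = pv + rng.normal(0.0, cfg.noise_sigma_pv, size=pv.shape)
        np.clip(np.rint(pv, out=pv), 0, pv_max, out=pv)
        frames[:, sl] = pv.astype(np.uint8).T
    return FrameStack(
        frames=frames.reshape(n_frames, h, w),
        fps=fps,
        pixel_pitch_mm=cfg.pixel_pitch_mm,
        beam_start_index=int(round(cfg.pre_roll_s * fps)),
    )


# ---------------------------------------------------------------------------
# Validation scenarios
# ---------------------------------------------------------------------------


def snake_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-major alternating delivery order: rows from +y down, serpentine x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ys = np.unique(y)[::-1]
    order: list[int] = []
    for r, yv in enumerate(ys):
        idx = np.flatnonzero(y == yv)
        idx = idx[np.argsort(x[idx])]
        if r % 2 == 1:
            idx = idx[::-1]
        order.extend(idx.tolist())
    return np.asarray(order)


def scenario_qa_grid(
    field_mm: float = 30.0,
    spacing_mm: float = 5.0,
    total_dose_gy: float = 15.0,
    current_nA: float = 120.0,
    machine: MachineModel | None = None,
) -> SpotList:
    """Uniform-MU QA grid: square field, snake-ordered spots.

    MU per spot is chosen so the superposed central-axis dose equals
    ``total_dose_gy`` under the machine model at the given nozzle current.
    """
    if not total_dose_gy > 0 or not current_nA > 0:
        raise ValueError("dose and current must be positive")
    machine = machine or MachineModel()
    n_steps = field_mm / spacing_mm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("spacing must divide the field extent")
    n = int(round(n_steps)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    xg, yg = np.meshgrid(coords, coords)
    x, y = xg.ravel(), yg.ravel()
    order = snake_order(x, y)
    x, y = x[order], y[order]
    pattern = SpotList(x, y, np.ones(x.size))
    ratio = field_to_spot_ratio(pattern, machine.spot_sigma_mm)
    mu = total_dose_gy / ratio / machine.dose_per_mu(current_nA)
    return SpotList(x, y, np.full(x.size, mu))


def scenario_revisit(
    n_steps: int,
    dose_per_target_gy: float = 10.0,
    current_nA: float = 120.0,
    machine: MachineModel | None = None,
    target_y_mm: tuple[float, float, float] = (15.0, 0.0, -15.0),
) -> SpotList:
    """Revisit pattern: three targets on the y axis, dose in equal installments.

    ``n_steps`` passes sweep the targets in a snake (alternating) order
    starting at +y; each target receives ``dose_per_target_gy`` in ``n_steps``
    equal parts, so the center target's accumulation plateaus at the
    1/n .. (n-1)/n levels between deliveries.
    """
    if n_steps not in (1, 2, 3):
        raise ValueError("n_steps must be 1, 2 or 3")
    machine = machine or MachineModel()
    ys: list[float] = []
    seq = list(target_y_mm)
    for p in range(n_steps):
        ys.extend(seq if p % 2 == 0 else seq[::-1])
    ys_arr = np.asarray(ys)
    xs = np.zeros(ys_arr.size)
    # neighbor cross-talk at 15 mm is exp(-15^2 / (2 sigma^2)) ~ 4e-4: ignored
    mu = dose_per_target_gy / n_steps / machine.dose_per_mu(current_nA)
    return SpotList(xs, ys_arr, np.full(ys_arr.size, mu))


def reorder_spot_list(spots: SpotList, order) -> SpotList:
    """Reorder delivery: ``order`` is a permutation of spot indices or "snake".

    Positions and MU are untouched; the final dose map is invariant, only the
    time structure (hence delta-t / PBS dose rate) changes.
    """
    if isinstance(order, str):
        if order != "snake":
            raise ValueError(f"unknown ordering keyword {order!r}")
        perm = snake_order(spots.x_mm, spots.y_mm)
    else:
        perm = np.asarray(order, dtype=int)
        if sorted(perm.tolist()) != list(range(len(spots))):
            raise ValueError("order is not a permutation of spot indices")
    return SpotList(spots.x_mm[perm], spots.y_mm[perm], spots.mu[perm])
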