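"""Delta-t and PBS dose rate from dose-accumulation-over-time.

The PBS (pencil-beam scanning) dose rate at a position follows the
Folkerts definition: the accumulation curve rises from D_min = 0 to D_max;
a threshold d marks a start point (D_min + d) and stop point (D_max - d),
and the dose rate is the ratio of the dose and time spans between them,
dD/dt.  With the default fractional threshold d = 10% the time span dt runs
from the 10% to the 90% crossing of the normalized accumulation.

Normalization uses the mean of the final tail window (1 s = 240 frames at
240 fps) as the 100% level, and crossings are found by linear interpolation
on the running-maximum envelope (accumulation is physically monotone; the
envelope makes crossings unique under noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import ScalarMap

__all__ = [
    "DeltaTParams",
    "DeltaTMap",
    "normalize_accumulation",
    "threshold_crossings",
    "delta_t_map",
    "pbs_dose_rate",
    "infield_mask",
    "delta_t_statistics",
]


@dataclass
class DeltaTParams:
    """Thresholds and tail window for delta-t extraction.

    ``lower_frac``/``upper_frac`` are the crossing levels as fractions of the
    tail-normalized maximum (0.10/0.90 for d = 10%); ``tail_window_s`` is the
    averaging window defining the 100% level; ``d_threshold`` is the PBS
    dose-rate threshold (fraction of D_max, or Gy in absolute mode).
    """

    lower_frac: float = 0.10
    upper_frac: float = 0.90
    tail_window_s: float = 1.0
    d_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.lower_frac < self.upper_frac < 1):
            raise ValueError("require 0 < lower_frac < upper_frac < 1")
        if not self.tail_window_s > 0:
            raise ValueError("tail_window_s must be positive")


@dataclass
class DeltaTMap:
    """Per-pixel delta-t [s] with the crossing times and a validity mask."""

    delta_t: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    mask: np.ndarray
    pixel_pitch_mm: float
    origin_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.any() and np.any(self.delta_t[self.mask] < 0):
            raise ValueError("delta_t must be >= 0 on masked-in pixels")
        self.origin_mm = (float(self.origin_mm[0]), float(self.origin_mm[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta_t.shape

    def as_scalar_map(self) -> ScalarMap:
        values = np.where(self.mask, self.delta_t, np.nan)
        return ScalarMap(
            values=values,
            pixel_pitch_mm=self.pixel_pitch_mm,
            origin_mm=self.origin_mm,
            mask=self.mask,
        )


def normalize_accumulation(curve, fps: float, tail_window_s: float = 1.0):
    """Scale an accumulation curve so the mean of its final tail window is 100.

    Returns ``(normalized_curve, tail_mean)``.  Raises when the curve does not
    cover the tail window or the tail mean is non-positive (a never-irradiated
    pixel; at map level such pixels are masked out instead).
    """
    curve = np.asarray(curve, dtype=float)
    n_tail = int(round(tail_window_s * fps))
    if curve.size <= n_tail:
        raise ValueError("curve shorter than the tail averaging window")
    tail = float(curve[-n_tail:].mean())
    if tail <= 0:
        raise ValueError("tail mean <= 0: pixel never irradiated")
    return curve * (100.0 / tail), tail


def _crossing_time(env: np.ndarray, level: float, fps: float) -> float:
    """First upward crossing of ``level`` on a monotone envelope, linearly
    interpolated between the bracketing samples (t = index / fps)."""
    idx = int(np.argmax(env >= level))
    if env[idx] < level:
        raise ValueError(f"threshold {level} never reached")
    if idx == 0:
        return 0.0
    lo, hi = env[idx - 1], env[idx]
    frac = (level - lo) / (hi - lo) if hi > lo else 1.0
    return (idx - 1 + frac) / fps


def threshold_crossings(
    curve_norm,
    fps: float,
    lower_frac: float = 0.10,
    upper_frac: float = 0.90,
) -> tuple[float, float]:
    """Times t1, t2 of the lower/upper threshold crossings on one curve.

    The curve must be normalized to 100 at the plateau; a running maximum is
    applied first so noise cannot create multiple crossings.
    """
    env = np.maximum.accumulate(np.asarray(curve_norm, dtype=float))
    t1 = _crossing_time(env, 100.0 * lower_frac, fps)
    t2 = _crossing_time(env, 100.0 * upper_frac, fps)
    return t1, t2


def _crossings_stack(env: np.ndarray, levels: np.ndarray, fps: float) -> np.ndarray:
    """Vectorized first-crossing times; env (T, P) monotone, levels (P,)."""
    n = env.shape[0]
    reached = env >= levels[None, :]
    idx = np.argmax(reached, axis=0)
    ok = reached[-1, :]
    idx_c = np.clip(idx, 1, n - 1)
    lo = np.take_along_axis(env, (idx_c - 1)[None, :], axis=0)[0]
    hi = np.take_along_axis(env, idx_c[None, :], axis=0)[0]
    denom = hi - lo
    frac = np.where(denom > 0, (levels - lo) / np.where(denom > 0, denom, 1.0), 1.0)
    t = (idx_c - 1 + frac) / fps
    t = np.where(idx == 0, 0.0, t)
    return np.where(ok, t, np.nan)


def delta_t_map(
    acc_stack: np.ndarray,
    fps: float,
    params: DeltaTParams | None = None,
    pixel_pitch_mm: float = 1.0,
    origin_mm: tuple[float, float] | None = None,
    mask_frac: float = 0.0,
) -> DeltaTMap:
    """Per-pixel delta-t from a ``(T, H, W)`` accumulation stack.

    Each pixel is tail-normalized and searched for its threshold crossings;
    pixels whose tail mean is not positive (or falls below ``mask_frac`` of
    the map's maximum tail) are masked out.
    """
    params = params or DeltaTParams()
    acc = np.asarray(acc_stack, dtype=float)
    if acc.ndim != 3:
        raise ValueError("acc_stack must be (T, H, W)")
    n_tail = int(round(params.tail_window_s * fps))
    t_len, h, w = acc.shape
    if t_len <= n_tail:
        raise ValueError("stack shorter than the tail averaging window")
    flat = acc.reshape(t_len, h * w)
    tail = flat[-n_tail:].mean(axis=0)
    valid = tail > max(mask_frac * tail.max(initial=0.0), 0.0)
    env = np.maximum.accumulate(flat, axis=0)
    levels1 = params.lower_frac * tail
    levels2 = params.upper_frac * tail
    t1 = _crossings_stack(env, levels1, fps)
    t2 = _crossings_stack(env, levels2, fps)
    valid &= np.isfinite(t1) & np.isfinite(t2)
    dt = np.where(valid, t2 - t1, np.nan)
    if origin_mm is None:
        origin_mm = (-w * pixel_pitch_mm / 2.0, -h * pixel_pitch_mm / 2.0)
    return DeltaTMap(
        delta_t=dt.reshape(h, w),
        t1=t1.reshape(h, w),
        t2=t2.reshape(h, w),
        mask=valid.reshape(h, w),
        pixel_pitch_mm=pixel_pitch_mm,
        origin_mm=origin_mm,
    )


def pbs_dose_rate(
    dtm: DeltaTMap,
    dose: ScalarMap | None = None,
    d: float = 0.10,
    absolute: bool = False,
) -> ScalarMap:
    """PBS dose rate dD/dt per pixel.

    Fractional threshold (default): dD = (1 - 2d) * D_max.  Absolute
    threshold (d in Gy, requires a dose map): dD = D_max - 2d.  Without a
    dose map the rate is relative, in %/s, with D_max = 100%.  Pixels with
    delta-t = 0 are masked out rather than divided.
    """
    if absolute and dose is None:
        raise ValueError("absolute threshold requires a dose map")
    if dose is not None:
        if dose.values.shape != dtm.shape:
            raise ValueError("dose map and delta-t map must be co-registered")
        d_max = dose.values
    else:
        d_max = np.full(dtm.shape, 100.0)
    if absolute:
        if np.any(d >= d_max[dtm.mask] / 2.0):
            raise ValueError("absolute threshold d >= D_max/2 at an evaluated pixel")
        delta_d = d_max - 2.0 * d
    else:
        delta_d = (1.0 - 2.0 * d) * d_max
    mask = dtm.mask & (dtm.delta_t > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(mask, delta_d / dtm.delta_t, np.nan)
    return ScalarMap(
        values=rate,
        pixel_pitch_mm=dtm.pixel_pitch_mm,
        origin_mm=dtm.origin_mm,
        mask=mask,
    )


def infield_mask(dose: ScalarMap, frac: float = 0.5) -> np.ndarray:
    """In-field (ICRU treatment field) mask: dose >= frac * max(dose).

    The default 50% isodose line defines the evaluated region.
    """
    vals = np.where(dose.mask, dose.values, -np.inf)
    vmax = vals.max()
    if not vmax > 0:
        raise ValueError("dose map has no positive maximum")
    return vals >= frac * vmax


def delta_t_statistics(dtm: DeltaTMap, mask: np.ndarray | None = None) -> dict:
    """Mean and 5th/50th/95th percentile of delta-t over masked-in pixels.

    Percentiles use linear interpolation between order statistics.
    """
    m = dtm.mask if mask is None else (dtm.mask & np.asarray(mask, dtype=bool))
    vals = dtm.delta_t[m]
    if vals.size == 0:
        raise ValueError("no masked-in pixels to summarize")
    p5, p50, p95 = np.percentile(vals, [5, 50, 95])
    return {
        "mean": float(vals.mean()),
        "p5": float(p5),
        "p50": float(p50),
        "p95": float(p95),
    }
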