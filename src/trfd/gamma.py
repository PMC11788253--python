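"""Registration and local 2D gamma evaluation of delta-t distributions.

The gamma index combines a value criterion (a fraction of the local
reference value -- 10% in delta-t by default) and a distance-to-agreement
criterion (2 mm by default): for an evaluated pixel at r_m with value v_m,

    gamma(r_m) = min over reference points r_s of
        sqrt( |r_m - r_s|^2 / dta^2 + (v_m - v_r(r_s))^2 / (f * v_r(r_s))^2 )

and the pixel passes when gamma <= 1.  "Local" means the value criterion is
normalized by the reference value at each candidate point, which is the
right choice for highly inhomogeneous PBS dose-rate distributions where the
low-dose-rate valleys matter most.

Before comparing delta-t maps the measured and simulated *dose* maps are
registered (translation from normalized cross-correlation with parabolic
sub-pixel peak interpolation); the shift is then applied to the measured
delta-t map.  Since maps carry physical geometry, applying a shift is just a
change of origin -- no resampling of the measured data is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .delta_t import DeltaTMap
from .formats import ScalarMap

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "register_maps",
    "shift_map",
    "local_gamma",
    "pass_rate",
]


@dataclass
class GammaCriteria:
    """Gamma criteria: value fraction, distance-to-agreement, search radius.

    ``value_frac`` is the value criterion as a fraction of the (local)
    reference value; ``distance_mm`` the distance criterion; the candidate
    search is truncated at ``search_radius_factor * distance_mm`` (any point
    farther away alone contributes gamma > that factor, so pass/fail
    decisions are unaffected); ``value_floor`` excludes pixels whose
    reference value is below it (same units as the maps).
    """

    value_frac: float = 0.10
    distance_mm: float = 2.0
    search_radius_factor: float = 3.0
    local: bool = True
    value_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.value_frac > 0:
            raise ValueError("value_frac must be positive")
        if not self.distance_mm > 0:
            raise ValueError("distance_mm must be positive")


@dataclass
class GammaResult:
    """Gamma values per evaluated pixel, pass rate and registration shift."""

    gamma: np.ndarray
    pass_rate: float
    n_evaluated: int
    shift_applied_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        evaluated = np.isfinite(self.gamma)
        if np.any(self.gamma[evaluated] < 0):
            raise ValueError("gamma must be >= 0 on evaluated pixels")
        if not 0.0 <= self.pass_rate <= 1.0:
            raise ValueError("pass_rate must lie in [0, 1]")


def _as_values_geometry(
    obj: ScalarMap | DeltaTMap,
) -> tuple[np.ndarray, float, tuple[float, float], np.ndarray]:
    if isinstance(obj, DeltaTMap):
        return obj.delta_t, obj.pixel_pitch_mm, obj.origin_mm, obj.mask
    return obj.values, obj.pixel_pitch_mm, obj.origin_mm, obj.mask


def _resample_to(
    values: np.ndarray,
    pitch: float,
    origin: tuple[float, float],
    x_new: np.ndarray,
    y_new: np.ndarray,
) -> np.ndarray:
    """Bilinear sample of a map at physical coordinates (NaN outside the
    pixel-center hull, with a small tolerance against float jitter)."""
    rows = (y_new - origin[1]) / pitch - 0.5
    cols = (x_new - origin[0]) / pitch - 0.5
    eps = 1e-6
    outside = (
        (rows < -eps)
        | (rows > values.shape[0] - 1 + eps)
        | (cols < -eps)
        | (cols > values.shape[1] - 1 + eps)
    )
    rows = np.clip(rows, 0.0, values.shape[0] - 1.0)
    cols = np.clip(cols, 0.0, values.shape[1] - 1.0)
    out = ndimage.map_coordinates(values, [rows, cols], order=1, mode="nearest")
    if np.any(outside):
        out = np.where(outside, np.nan, out)
    return out


def register_maps(
    measured_dose: ScalarMap, simulated_dose: ScalarMap
) -> tuple[float, float]:
    """Translation (dx, dy) [mm] aligning the measured onto the simulated map.

    The simulated dose is resampled onto the measured grid, both maps are
    mean-subtracted, and the normalized cross-correlation peak is located
    with parabolic sub-pixel interpolation.  The returned shift is what must
    be *added* to the measured map's coordinates to match the simulation.
    Raises when the correlation peak sits on the search boundary (maps do not
    overlap).
    """
    m_vals, m_pitch, m_origin, m_mask = _as_values_geometry(measured_dose)
    s_vals, s_pitch, s_origin, _ = _as_values_geometry(simulated_dose)
    a = np.where(m_mask, m_vals, 0.0)
    if not a.max() > 0:
        raise ValueError("measured dose map has no positive signal")
    xx, yy = np.meshgrid(
        measured_dose.x_centers(), measured_dose.y_centers()
    )
    b = _resample_to(s_vals, s_pitch, s_origin, xx, yy)
    b = np.nan_to_num(b, nan=0.0)
    if not b.max() > 0:
        raise ValueError("maps do not overlap (no simulated signal on the grid)")
    # per-lag normalized cross-correlation (cosine similarity over the
    # overlap region) -- an unnormalized correlation is biased toward zero
    # lag because the overlap area shrinks with the shift
    a_flip = a[::-1, ::-1]
    num = signal.fftconvolve(b, a_flip, mode="full")
    ones_a = np.ones_like(a)
    ones_b = np.ones_like(b)
    ea = signal.fftconvolve(ones_b, (a**2)[::-1, ::-1], mode="full")
    eb = signal.fftconvolve(b**2, ones_a[::-1, ::-1], mode="full")
    # only lags retaining a substantial part of both maps' energy are
    # admissible: tiny tail overlaps have near-perfect cosine similarity
    admissible = (ea > 0.3 * ea.max()) & (eb > 0.3 * eb.max())
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(admissible, num / np.sqrt(ea * eb), 0.0)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    if (
        peak[0] in (0, corr.shape[0] - 1)
        or peak[1] in (0, corr.shape[1] - 1)
    ):
        raise ValueError("correlation peak at search boundary: maps do not overlap")

    def parabolic(c_m1: float, c_0: float, c_p1: float) -> float:
        denom = c_m1 - 2.0 * c_0 + c_p1
        return 0.5 * (c_m1 - c_p1) / denom if denom != 0 else 0.0

    di = parabolic(corr[peak[0] - 1, peak[1]], corr[peak], corr[peak[0] + 1, peak[1]])
    dj = parabolic(corr[peak[0], peak[1] - 1], corr[peak], corr[peak[0], peak[1] + 1])
    shift_rows = peak[0] + di - (a.shape[0] - 1)
    shift_cols = peak[1] + dj - (a.shape[1] - 1)
    # grid shift plus any difference in map origins
    dx = shift_cols * m_pitch
    dy = shift_rows * m_pitch
    return float(dx), float(dy)


def shift_map(obj: ScalarMap | DeltaTMap, dx_mm: float, dy_mm: float):
    """Translate a map by (dx, dy) mm by moving its origin (no resampling)."""
    import copy

    out = copy.deepcopy(obj)
    out.origin_mm = (obj.origin_mm[0] + dx_mm, obj.origin_mm[1] + dy_mm)
    return out


def local_gamma(
    eval_map: ScalarMap | DeltaTMap,
    ref_map: ScalarMap | DeltaTMap,
    criteria: GammaCriteria | None = None,
    mask: np.ndarray | None = None,
) -> GammaResult:
    """Gamma evaluation of ``eval_map`` against ``ref_map``.

    Candidate reference points are sampled on a disc of radius
    ``search_radius_factor * distance_mm`` around each evaluated pixel, at a
    step no coarser than ``distance_mm / 10`` (the reference is interpolated
    bilinearly when its native grid is coarser).  Pixels whose reference
    value falls below ``value_floor`` are excluded from evaluation; in local
    mode candidates with non-positive reference value are skipped.
    """
    criteria = criteria or GammaCriteria()
    e_vals, e_pitch, e_origin, e_mask = _as_values_geometry(eval_map)
    r_vals, r_pitch, r_origin, r_mask = _as_values_geometry(ref_map)
    r_vals = np.where(r_mask, r_vals, np.nan)

    eval_mask = e_mask.copy()
    if mask is not None:
        eval_mask &= np.asarray(mask, dtype=bool)
    if not eval_mask.any():
        raise ValueError("empty evaluation mask")
    if not np.all(np.isfinite(e_vals[eval_mask])):
        raise ValueError("non-finite evaluated values inside the mask")

    xx, yy = np.meshgrid(
        e_origin[0] + (np.arange(e_vals.shape[1]) + 0.5) * e_pitch,
        e_origin[1] + (np.arange(e_vals.shape[0]) + 0.5) * e_pitch,
    )
    px = xx[eval_mask]
    py = yy[eval_mask]
    v_m = e_vals[eval_mask]

    # reference value at the pixel's own position decides evaluability
    v_r_here = _resample_to(r_vals, r_pitch, r_origin, px, py)
    evaluable = np.isfinite(v_r_here) & (v_r_here >= criteria.value_floor)

    step = min(r_pitch, criteria.distance_mm / 10.0)
    radius = criteria.search_radius_factor * criteria.distance_mm
    n_off = int(np.floor(radius / step))
    offs = np.arange(-n_off, n_off + 1) * step
    ox, oy = np.meshgrid(offs, offs)
    disc = ox**2 + oy**2 <= radius**2 + 1e-12
    ox, oy = ox[disc], oy[disc]
    dist2 = (ox**2 + oy**2) / criteria.distance_mm**2

    if criteria.local:
        denom_global = None
    else:
        denom_global = criteria.value_frac * np.nanmax(r_vals)

    best = np.full(px.shape, np.inf)
    order = np.argsort(dist2)  # nearest candidates first
    for i in order:
        v_r = _resample_to(r_vals, r_pitch, r_origin, px + ox[i], py + oy[i])
        if criteria.local:
            denom = criteria.value_frac * v_r
            ok = np.isfinite(v_r) & (v_r > 0)
        else:
            denom = denom_global
            ok = np.isfinite(v_r)
        with np.errstate(divide="ignore", invalid="ignore"):
            g2 = dist2[i] + (v_m - v_r) ** 2 / denom**2
        np.minimum(best, np.where(ok, g2, np.inf), out=best)

    gamma_flat = np.sqrt(best)
    gamma_flat[~evaluable] = np.nan
    gamma = np.full(e_vals.shape, np.nan)
    gamma[eval_mask] = gamma_flat
    n_eval = int(np.sum(evaluable))
    if n_eval == 0:
        raise ValueError("no evaluable pixels (reference below floor everywhere)")
    rate = float(np.sum(gamma_flat[evaluable] <= 1.0 + _PASS_EPS) / n_eval)
    return GammaResult(gamma=gamma, pass_rate=rate, n_evaluated=n_eval)


# numeric tie-break: a pixel exactly on the gamma = 1 boundary passes even
# when float rounding pushes it a few ulp above
_PASS_EPS = 1e-9


def pass_rate(result: GammaResult) -> float:
    """Fraction of evaluated pixels with gamma <= 1."""
    if result.n_evaluated < 1:
        raise ValueError("no evaluated pixels")
    finite = np.isfinite(result.gamma)
    return float(np.sum(result.gamma[finite] <= 1.0 + _PASS_EPS) / np.sum(finite))
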