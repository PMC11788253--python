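"""Pixel value -> optical density -> relative dose.

Transmission densitometry with the full-scale white level as reference:
``OD = log10(2^b / (PV + 1))`` for a ``b``-bit channel, so a saturated pixel
(PV = 2^b - 1) has OD = 0 and OD increases as the film darkens.  Net OD is
taken relative to the first recorded frame (pre-irradiation reference).

The OD-to-dose calibration is the three-term curve

    D(OD_net) = a + b * OD_net + c * OD_net**m

fitted by trust-region nonlinear least squares.  For conventional flatbed
scans a 2D polynomial (OD order 0-3 x lateral-position order 0-2) absorbs
the scanner's lateral response on top of the OD-to-dose relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .formats import FrameStack

__all__ = [
    "CalibrationParams",
    "ScannerCalibration",
    "pv_to_od",
    "od_to_pv",
    "net_od",
    "fit_od_to_dose",
    "apply_calibration",
    "invert_calibration",
    "fit_scanner_calibration",
    "apply_scanner_calibration",
]


@dataclass
class CalibrationParams:
    """Parameters of the OD-to-dose curve D = a + b*OD + c*OD**m.

    ``a`` [Gy] intercept, ``b`` [Gy/OD] linear coefficient, ``c`` [Gy/OD^m]
    power coefficient, ``m`` dimensionless exponent.  ``od_max`` is the upper
    end of the fitted (hence invertible) OD range; ``m_identifiable`` is False
    when the data carried no curvature so the power term is arbitrary.
    """

    a: float
    b: float
    c: float
    m: float
    od_max: float = 2.5
    rms: float = 0.0
    m_identifiable: bool = True

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "m": self.m,
            "od_max": self.od_max,
            "rms": self.rms,
            "m_identifiable": self.m_identifiable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParams":
        return cls(**d)


@dataclass
class ScannerCalibration:
    """2D polynomial dose model for flatbed scans.

    ``coeffs[i, j]`` multiplies ``OD**i * lateral_mm**j`` with OD order 0-3
    and lateral order 0-2.
    """

    coeffs: np.ndarray = field(default_factory=lambda: np.zeros((4, 3)))

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (4, 3):
            raise ValueError("coeffs must have shape (4, 3): OD order 0-3 x lateral 0-2")


#: OD-to-dose curve for EBT-XD film read out through the 8-bit red channel
#: of the time-resolved setup (fit over 0-50 Gy; relative dose scale).
REFERENCE_CALIBRATION = CalibrationParams(
    a=-7.48e-3, b=24.5, c=33.5, m=1.80, od_max=2.5
)


def pv_to_od(pv, bit_depth: int = 8) -> np.ndarray:
    """Optical density of an integer pixel value: log10(2^b / (PV + 1))."""
    pv = np.asarray(pv, dtype=float)
    full = float(2**bit_depth)
    if np.any(pv < 0) or np.any(pv > full - 1):
        raise ValueError(f"pixel values must lie in [0, {int(full) - 1}]")
    return np.log10(full / (pv + 1.0))


def od_to_pv(od, bit_depth: int = 8, round_int: bool = False) -> np.ndarray:
    """Inverse of :func:`pv_to_od`: PV = 2^b / 10^OD - 1 (float unless rounded)."""
    od = np.asarray(od, dtype=float)
    pv = float(2**bit_depth) / np.power(10.0, od) - 1.0
    if round_int:
        pv = np.clip(np.rint(pv), 0, 2**bit_depth - 1).astype(np.int64)
    return pv


def net_od(stack: FrameStack, bit_depth: int = 8) -> np.ndarray:
    """Per-pixel net OD time series: OD(frame t) - OD(first frame).

    Returns a float ``(T, H, W)`` array; the first frame is exactly zero.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to form a net OD series")
    od = pv_to_od(stack.frames, bit_depth=bit_depth)
    return od - od[0]


def apply_calibration(od_net, params: CalibrationParams, neg_tol: float = 0.05):
    """Evaluate D = a + b*OD_net + c*OD_net**m elementwise.

    Small negative OD_net from noise (down to ``-neg_tol``) is clipped to 0
    before the fractional power; values below the tolerance raise.
    """
    od_net = np.asarray(od_net, dtype=float)
    if np.any(od_net < -neg_tol):
        raise ValueError(f"od_net below -{neg_tol} is outside the calibrated range")
    od = np.clip(od_net, 0.0, None)
    out = params.a + params.b * od + params.c * np.power(od, params.m)
    return out if out.ndim else float(out)


def _dose_bounds(params: CalibrationParams) -> tuple[float, float]:
    lo = apply_calibration(0.0, params)
    hi = apply_calibration(params.od_max, params)
    return lo, hi


def invert_calibration(dose, params: CalibrationParams):
    """OD_net at which the calibration curve reaches ``dose``.

    Scalars are solved by bisection (Brent) on the monotone branch; arrays use
    a dense lookup table refined by one vectorized Newton step.  Round trip
    ``apply(invert(D)) == D`` holds to ~1e-12 Gy.
    """
    lo, hi = _dose_bounds(params)
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < lo - 1e-12) or np.any(dose_arr > hi + 1e-12):
        raise ValueError(
            f"dose outside the calibrated range [{lo:.4g}, {hi:.4g}] Gy"
        )
    if dose_arr.ndim == 0:
        return float(
            optimize.brentq(
                lambda od: apply_calibration(od, params) - float(dose_arr),
                0.0,
                params.od_max,
                xtol=1e-15,
                rtol=8.9e-16,
            )
        )
    od_grid = np.linspace(0.0, params.od_max, 1 << 20)
    d_grid = params.a + params.b * od_grid + params.c * np.power(od_grid, params.m)
    od = np.interp(dose_arr, d_grid, od_grid)
    # one Newton step; derivative b + c*m*od^(m-1) > 0 on the monotone branch
    f = params.a + params.b * od + params.c * np.power(od, params.m) - dose_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        deriv = params.b + params.c * params.m * np.power(od, params.m - 1.0)
    step = np.where(np.isfinite(deriv) & (deriv > 0), f / deriv, 0.0)
    return np.clip(od - step, 0.0, params.od_max)


def fit_od_to_dose(
    od_net,
    dose_gy,
    m_bounds: tuple[float, float] = (1.0, 5.0),
) -> CalibrationParams:
    """Least-squares fit of the OD-to-dose curve to (OD_net, dose) points.

    Needs >= 5 points spanning a monotone OD range including near zero.
    Initialization: a = 0, b from a linear prefit, c = 1, m = 2.  If the data
    are purely linear the power term is unidentifiable; c is set to 0 and the
    ``m_identifiable`` flag cleared.
    """
    od = np.asarray(od_net, dtype=float).ravel()
    dose = np.asarray(dose_gy, dtype=float).ravel()
    if od.size != dose.size:
        raise ValueError("od_net and dose must have equal length")
    if od.size < 5:
        raise ValueError("need at least 5 calibration points (4 free parameters)")
    if np.any(od < 0):
        raise ValueError("calibration OD_net values must be non-negative")
    od_max = float(od.max())
    if od_max <= 0:
        raise ValueError("calibration points span no OD range")

    # linear prefit for scale and a degenerate-linearity check
    b0, a0 = np.polyfit(od, dose, 1)
    lin_res = dose - (a0 + b0 * od)
    scale = max(np.abs(dose).max(), 1.0)
    if np.sqrt(np.mean(lin_res**2)) < 1e-9 * scale:
        return CalibrationParams(
            a=float(a0), b=float(b0), c=0.0, m=2.0,
            od_max=od_max, rms=float(np.sqrt(np.mean(lin_res**2))),
            m_identifiable=False,
        )

    def resid(theta):
        a, b, c, m = theta
        return a + b * od + c * np.power(od, m) - dose

    lo = np.array([-np.inf, -np.inf, -np.inf, m_bounds[0] + 1e-9])
    hi = np.array([np.inf, np.inf, np.inf, m_bounds[1]])
    sol = optimize.least_squares(
        resid, x0=[0.0, b0, 1.0, 2.0], bounds=(lo, hi), xtol=1e-15, ftol=1e-15
    )
    a, b, c, m = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    params = CalibrationParams(
        a=float(a), b=float(b), c=float(c), m=float(m), od_max=od_max, rms=rms
    )
    # the fitted curve must be increasing on the fitted range
    probe = np.linspace(0, od_max, 256)
    d_probe = apply_calibration(probe, params)
    if np.any(np.diff(d_probe) <= 0):
        raise ValueError("fitted calibration curve is not increasing on the OD range")
    if abs(c) < 1e-6 * max(abs(b), 1.0):
        params.m_identifiable = False
    return params


# ---------------------------------------------------------------------------
# Flatbed scanner calibration (conventional film dosimetry)
# ---------------------------------------------------------------------------


def _scanner_design(od: np.ndarray, lateral: np.ndarray) -> np.ndarray:
    cols = [od**i * lateral**j for i in range(4) for j in range(3)]
    return np.stack(cols, axis=-1)


def fit_scanner_calibration(od_net, lateral_mm, dose_gy) -> ScannerCalibration:
    """2D polynomial fit: dose ~ sum c_ij OD^i lateral^j (i<=3, j<=2).

    Samples must cover >= 3 distinct lateral positions and >= 4 OD levels.
    """
    od = np.asarray(od_net, dtype=float).ravel()
    lat = np.asarray(lateral_mm, dtype=float).ravel()
    dose = np.asarray(dose_gy, dtype=float).ravel()
    if not (od.size == lat.size == dose.size):
        raise ValueError("od_net, lateral_mm, dose must have equal length")
    if np.unique(lat).size < 3:
        raise ValueError("need samples at >= 3 lateral scan positions")
    if np.unique(od).size < 4:
        raise ValueError("need samples at >= 4 OD levels")
    design = _scanner_design(od, lat)
    coef, *_ = np.linalg.lstsq(design, dose, rcond=None)
    return ScannerCalibration(coeffs=coef.reshape(4, 3))


def apply_scanner_calibration(od_net, lateral_mm, cal: ScannerCalibration):
    """Evaluate the flatbed calibration at (OD_net, lateral position)."""
    od = np.asarray(od_net, dtype=float)
    lat = np.asarray(lateral_mm, dtype=float)
    od, lat = np.broadcast_arrays(od, lat)
    out = np.zeros(od.shape)
    for i in range(4):
        for j in range(3):
            out += cal.coeffs[i, j] * od**i * lat**j
    return out if out.ndim else float(out)
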