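"""Post-irradiation coloration kinetics: model, fit, convolve, deconvolve.

Radiochromic film keeps darkening after the beam stops.  The model assumes
every instantaneous dose deposit produces the same logarithmic-in-time
response kernel

    k(t) = offset + c_slope * log10(t + a_shift)

so the recorded film response of a pixel is the causal discrete convolution
of the delivered pulse train with k.  Undoing the coloration is then a
deconvolution: the forward operator is a lower-triangular Toeplitz matrix
whose first column is the sampled kernel, solved exactly with Levinson
recursion (or ridge-regularized least squares for noisy short curves).
The running integral of the recovered pulse is the relative
dose-accumulation-over-time used for delta-t extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, signal

__all__ = [
    "ResponseFunction",
    "PulseTrain",
    "ResponseCurve",
    "eval_kernel",
    "sample_kernel",
    "convolve_response",
    "deconvolve_response",
    "inverse_filter",
    "deconvolve_stack",
    "accumulate",
    "fit_response_function",
    "block_pulse",
]


@dataclass
class ResponseFunction:
    """Film response kernel k(t) = offset + c_slope * log10(t + a_shift).

    ``a_shift`` [s] shifts the log singularity off t = 0 and sets the early
    response gradient; ``c_slope`` [1/decade] is the late response gradient;
    ``duration_s`` is the kernel support used when discretizing (the film
    stabilization window, 60 s by default).
    """

    offset: float
    a_shift: float
    c_slope: float
    duration_s: float = 60.0
    rms: float = 0.0

    def __post_init__(self) -> None:
        if not self.a_shift > 0:
            raise ValueError("a_shift must be positive (log argument at t=0)")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")

    def to_dict(self) -> dict:
        return {
            "offset": self.offset,
            "a_shift": self.a_shift,
            "c_slope": self.c_slope,
            "duration_s": self.duration_s,
            "rms": self.rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseFunction":
        return cls(**d)


#: Coloration kernel of EBT-XD film as seen by the 240 fps red-channel
#: readout: offset, early response gradient a [s], late response gradient c.
REFERENCE_RESPONSE_FUNCTION = ResponseFunction(
    offset=7.5e-3, a_shift=5.4e-2, c_slope=5.7e-4, duration_s=60.0
)


@dataclass
class PulseTrain:
    """Dose (or current) deposited per sample at a fixed sample rate."""

    sample_rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        self.values = np.asarray(self.values, dtype=float)

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate_hz


@dataclass
class ResponseCurve:
    """Relative dose reading per time step (film response)."""

    sample_rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        self.values = np.asarray(self.values, dtype=float)

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate_hz


def eval_kernel(rf: ResponseFunction, times) -> np.ndarray:
    """Kernel values k(t) at times >= 0 [s]."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal: times must be >= 0")
    out = rf.offset + rf.c_slope * np.log10(t + rf.a_shift)
    return out if out.ndim else float(out)


def sample_kernel(rf: ResponseFunction, sample_rate_hz: float, n_max: int | None = None) -> np.ndarray:
    """Kernel discretized at t = i / fs, i = 0..ceil(duration_s * fs).

    ``n_max`` caps the length at the record length (the kernel is truncated
    to the support it can causally contribute within the record).
    """
    n = int(np.ceil(rf.duration_s * sample_rate_hz)) + 1
    if n_max is not None:
        n = min(n, n_max)
    return eval_kernel(rf, np.arange(n) / sample_rate_hz)


def convolve_response(pulse: PulseTrain, rf: ResponseFunction) -> ResponseCurve:
    """Causal discrete convolution: response[n] = sum_{i<=n} pulse[i] k[n-i].

    The output has the pulse's length (full causal support, truncated at the
    record end).
    """
    n = pulse.values.size
    k = sample_kernel(rf, pulse.sample_rate_hz, n_max=n)
    y = signal.fftconvolve(pulse.values, k)[:n]
    return ResponseCurve(sample_rate_hz=pulse.sample_rate_hz, values=y)


def _toeplitz_column(rf: ResponseFunction, fs: float, n: int) -> np.ndarray:
    k = sample_kernel(rf, fs, n_max=n)
    col = np.zeros(n)
    col[: k.size] = k
    return col


def inverse_filter(rf: ResponseFunction, sample_rate_hz: float, n: int) -> np.ndarray:
    """First column g of the inverse of the causal convolution operator.

    The inverse of a lower-triangular Toeplitz matrix is lower-triangular
    Toeplitz; applying the deconvolution to any response is then a causal
    convolution with g.  Raises if the kernel's leading sample is zero.
    """
    col = _toeplitz_column(rf, sample_rate_hz, n)
    if col[0] == 0:
        raise ValueError("kernel leading sample is zero: system not invertible")
    e0 = np.zeros(n)
    e0[0] = 1.0
    row = np.zeros(n)
    row[0] = col[0]
    return linalg.solve_toeplitz((col, row), e0)


def deconvolve_response(
    response: ResponseCurve,
    rf: ResponseFunction,
    reg_lambda: float = 0.0,
    smooth_window_s: float = 0.0,
) -> PulseTrain:
    """Recover the delivered pulse from a film response.

    With ``reg_lambda = 0`` this is the exact forward solve of the causal
    lower-triangular Toeplitz system (Levinson): re-convolving the result
    reproduces the (smoothed) input to machine precision.  ``reg_lambda > 0``
    switches to ridge-regularized least squares (dense; meant for short,
    noisy curves).  ``smooth_window_s`` applies a moving average before
    deconvolution.  The recovered pulse is not forced non-negative: noise maps
    to sign-alternating pulse samples and clipping would bias delta-t.
    """
    y = response.values
    n = y.size
    if n < 2:
        raise ValueError("response must have at least 2 samples")
    fs = response.sample_rate_hz
    if smooth_window_s > 0:
        w = max(int(round(smooth_window_s * fs)), 1)
        y = np.convolve(y, np.ones(w) / w, mode="same")
    col = _toeplitz_column(rf, fs, n)
    if col[0] == 0:
        raise ValueError("kernel leading sample is zero: system not invertible")
    if reg_lambda == 0:
        row = np.zeros(n)
        row[0] = col[0]
        x = linalg.solve_toeplitz((col, row), y)
    else:
        t_mat = linalg.toeplitz(col, np.zeros(n))
        x = np.linalg.solve(
            t_mat.T @ t_mat + reg_lambda * np.eye(n), t_mat.T @ y
        )
    return PulseTrain(sample_rate_hz=fs, values=x)


def deconvolve_stack(
    responses: np.ndarray, rf: ResponseFunction, sample_rate_hz: float
) -> np.ndarray:
    """Exact deconvolution of many pixels sharing one kernel.

    ``responses`` is ``(P, N)`` with time along the last axis.  The inverse
    filter is computed once and applied to all pixels with FFT convolution.
    """
    responses = np.asarray(responses)
    n = responses.shape[-1]
    g = inverse_filter(rf, sample_rate_hz, n)
    out = signal.fftconvolve(responses, g[None, :], axes=-1)[..., :n]
    return out


def accumulate(pulse: PulseTrain) -> np.ndarray:
    """Relative dose accumulation: running cumulative sum of the pulse.

    Pulse values are dose deposited per sample, so the final value is the
    total delivered dose.
    """
    return np.cumsum(pulse.values)


def block_pulse(
    amplitude: float,
    duration_s: float,
    sample_rate_hz: float,
    total_s: float,
    start_s: float = 0.0,
) -> PulseTrain:
    """Rectangular pulse of ``amplitude`` per sample over [start, start+duration)."""
    n = int(round(total_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    values = np.where((t >= start_s) & (t < start_s + duration_s), amplitude, 0.0)
    return PulseTrain(sample_rate_hz=sample_rate_hz, values=values)


def fit_response_function(
    response: ResponseCurve,
    pulse: PulseTrain,
    duration_s: float = 60.0,
    x0: tuple[float, float, float] | None = None,
) -> ResponseFunction:
    """Fit (offset, a_shift, c_slope) so that pulse (x) k matches the response.

    The pulse must be known (e.g. a block pulse from the beam monitor); the
    kernel scale is then identifiable.  Initialization: offset from the
    response tail over the pulse area, a_shift = 0.05 s, c_slope = 1e-3;
    a_shift bounded to (1e-4, 10] s.
    """
    if pulse.sample_rate_hz != response.sample_rate_hz:
        raise ValueError("pulse and response must share the sample rate")
    if not np.any(pulse.values != 0):
        raise ValueError("pulse is identically zero: kernel not identifiable")
    fs = response.sample_rate_hz
    y = response.values
    n = y.size
    if n < 8:
        raise ValueError("response too short to fit a kernel")
    p = np.zeros(n)
    m = min(pulse.values.size, n)
    p[:m] = pulse.values[:m]
    if pulse.values.size > n:
        warnings.warn("pulse longer than response; trailing samples ignored")
    area = p.sum()
    tail = float(np.mean(y[-max(n // 20, 1):]))
    if x0 is None:
        x0 = (max(tail / area, 1e-6), 0.05, 1e-3)

    def model(theta):
        offset, a_shift, c_slope = theta
        k = eval_kernel(
            ResponseFunction(offset, a_shift, c_slope, duration_s),
            np.arange(min(int(np.ceil(duration_s * fs)) + 1, n)) / fs,
        )
        return signal.fftconvolve(p, k)[:n]

    sol = optimize.least_squares(
        lambda th: model(th) - y,
        x0=np.asarray(x0, dtype=float),
        bounds=([0.0, 1e-4, 0.0], [np.inf, 10.0, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
    )
    offset, a_shift, c_slope = sol.x
    return ResponseFunction(
        offset=float(offset),
        a_shift=float(a_shift),
        c_slope=float(c_slope),
        duration_s=duration_s,
        rms=float(np.sqrt(np.mean(sol.fun**2))),
    )
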