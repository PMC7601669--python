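"""Trace conditioning: low-pass filtering and baseline correction.

Raw patch-clamp recordings are conditioned in two steps before event
detection:

1. a zero-phase (forward-backward) Butterworth low-pass filter removes
   high-frequency noise while preserving the timing of event edges, which
   the slope features depend on;
2. a long-window Savitzky-Golay smoother estimates the slowly drifting
   open-pore baseline current I0; subtracting the filtered trace from this
   baseline yields the *deviation* series on which events are detected.

Sign convention: ``deviation = baseline - current``, so current blockades
(transient decreases) are positive excursions, and detection thresholds and
slopes are defined on the deviation.

Edge handling: the Savitzky-Golay window is truncated symmetrically near the
trace edges, with a per-position least-squares fit on the truncated window.
The first/last ``side_points`` samples are flagged via
:attr:`BaselineModel.edge_margin` so that events overlapping them can be
discarded downstream; with multi-thousand-point windows the edges are a
meaningful fraction of short traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trace import CurrentTrace

__all__ = [
    "BaselineModel",
    "lowpass_butterworth",
    "estimate_baseline_savgol",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_FILTER_ORDER",
    "DEFAULT_SIDE_POINTS",
    "DEFAULT_SG_ORDER",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 2500.0
DEFAULT_FILTER_ORDER = 2
DEFAULT_SIDE_POINTS = 2400
DEFAULT_SG_ORDER = 1


@dataclass
class BaselineModel:
    """Per-sample baseline estimate and deviation series for one trace.

    ``deviation = baseline - current``; blockades are positive excursions.
    ``edge_margin`` counts the leading/trailing samples whose baseline was
    fitted on a truncated window and should not contain accepted events.
    """

    baseline: np.ndarray
    deviation: np.ndarray
    edge_margin: int

    def __post_init__(self) -> None:
        if self.baseline.shape != self.deviation.shape:
            raise ValueError("baseline and deviation must have the same shape")


def lowpass_butterworth(
    trace: CurrentTrace,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> CurrentTrace:
    """Zero-phase Butterworth low-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``), which
    cancels phase distortion and preserves event onset timing at the cost of
    doubling the attenuation in dB: a sinusoid exactly at the cutoff comes
    out at half its input amplitude (two passes through the -3 dB point).

    Parameters
    ----------
    cutoff
        -3 dB frequency of a single pass, in Hz; must be below Nyquist.
    order
        Filter order of a single pass.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={nyquist:g} Hz), got {cutoff:g} Hz"
        )
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return CurrentTrace(filtered, trace.sampling_rate, trace.start_time)


def _sg_interior(x: np.ndarray, side_points: int, poly_order: int) -> np.ndarray:
    """Savitzky-Golay smoothing of the interior via overlap-add convolution."""
    window = 2 * side_points + 1
    coeffs = signal.savgol_coeffs(window, poly_order)
    # Smoothing coefficients are symmetric, so convolution == correlation.
    return signal.oaconvolve(x, coeffs, mode="valid")


def _sg_edges(x: np.ndarray, side_points: int, poly_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position least-squares fits on symmetrically truncated edge windows.

    At distance ``i`` from an edge the window is ``x[edge .. edge +/- 2i]``
    (2i+1 points, centered).  Evaluated at the window center the fit of any
    polynomial of degree <= poly_order reproduces polynomial inputs of that
    degree exactly, so e.g. a linear drift ramp is preserved at the edges.
    """
    n = x.size
    k = min(side_points, (n - 1) // 2)
    if poly_order <= 1:
        # Centered fit of degree <= 1 evaluated at the center == window mean.
        csum = np.concatenate(([0.0], np.cumsum(x)))
        i = np.arange(k)
        left = (csum[2 * i + 1] - csum[0]) / (2 * i + 1)
        right = (csum[n] - csum[n - (2 * i + 1)]) / (2 * i + 1)
        return left, right[::-1]
    left = np.empty(k)
    right = np.empty(k)
    for i in range(k):
        deg = min(poly_order, 2 * i)
        t = np.arange(-i, i + 1, dtype=float)
        left[i] = np.polynomial.polynomial.polyfit(t, x[: 2 * i + 1], deg)[0]
        right[i] = np.polynomial.polynomial.polyfit(t, x[n - 2 * i - 1 :], deg)[0]
    return left, right[::-1]


def estimate_baseline_savgol(
    trace: CurrentTrace,
    side_points: int = DEFAULT_SIDE_POINTS,
    poly_order: int = DEFAULT_SG_ORDER,
) -> BaselineModel:
    """Estimate the drifting open-pore baseline with a Savitzky-Golay smoother.

    ``side_points`` is the half-window: the full smoothing window is
    ``2 * side_points + 1`` samples (the default 2400 side points give a
    4801-point window, 48 ms at 100 kHz).  With ``poly_order=1`` the
    smoother reproduces any linear drift exactly while averaging out both
    noise and millisecond-scale blockades, whose durations are far shorter
    than the window.

    Returns the baseline together with ``deviation = baseline - current``.
    """
    if side_points < 1:
        raise ValueError(f"side_points must be >= 1, got {side_points}")
    if poly_order < 0 or poly_order > 2 * side_points:
        raise ValueError(f"poly_order {poly_order} invalid for window {2 * side_points + 1}")
    window = 2 * side_points + 1
    x = trace.samples
    if x.size <= window:
        raise ValueError(
            f"trace length {x.size} must exceed the smoothing window {window}"
        )
    baseline = np.empty_like(x)
    baseline[side_points:-side_points] = _sg_interior(x, side_points, poly_order)
    left, right = _sg_edges(x, side_points, poly_order)
    baseline[:side_points] = left
    baseline[-side_points:] = right
    deviation = baseline - x
    logger.debug(
        "baseline estimated: window=%d poly_order=%d edge_margin=%d",
        window, poly_order, side_points,
    )
    return BaselineModel(baseline=baseline, deviation=deviation, edge_margin=side_points)
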