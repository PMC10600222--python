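"""Zero-phase Butterworth filtering helpers.

All filters in the pipeline are 4th-order Butterworth applied
forward-backward (``scipy.signal.filtfilt``), so onset estimates carry no
group-delay bias.  Cutoffs are clipped just below Nyquist so that traces
sampled barely above a requested band still pass through unchanged rather
than erroring.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import SignalTrace

_ORDER = 4


def _clip_cut(cut: float, rate: float) -> float:
    nyq = rate / 2.0
    return min(cut, 0.99 * nyq)


def lowpass(trace: SignalTrace, cutoff: float) -> SignalTrace:
    sos = signal.butter(_ORDER, _clip_cut(cutoff, trace.rate),
                        btype="low", fs=trace.rate, output="sos")
    y = signal.sosfiltfilt(sos, trace.samples)
    return SignalTrace(y, trace.rate, trace.t0, trace.label, trace.units)


def highpass(trace: SignalTrace, cutoff: float) -> SignalTrace:
    sos = signal.butter(_ORDER, _clip_cut(cutoff, trace.rate),
                        btype="high", fs=trace.rate, output="sos")
    y = signal.sosfiltfilt(sos, trace.samples)
    return SignalTrace(y, trace.rate, trace.t0, trace.label, trace.units)


def bandpass(trace: SignalTrace, low: float, high: float) -> SignalTrace:
    hi = _clip_cut(high, trace.rate)
    if low >= hi:
        raise ValueError(f"band ({low}, {high}) empty at rate {trace.rate}")
    sos = signal.butter(_ORDER, (low, hi), btype="band",
                        fs=trace.rate, output="sos")
    if trace.samples.size <= 3 * (2 * sos.shape[0] + 1):
        raise ValueError("trace shorter than filter warm-up")
    y = signal.sosfiltfilt(sos, trace.samples)
    return SignalTrace(y, trace.rate, trace.t0, trace.label, trace.units)


def lowpass_array(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase low-pass for bare arrays (e.g. autocorrelation sequences)."""
    sos = signal.butter(_ORDER, _clip_cut(cutoff, rate),
                        btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)
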