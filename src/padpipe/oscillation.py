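"""Screening motor output for oscillations after movement onset.

Torque is band-pass filtered 3–100 Hz and EMG 3–200 Hz (no
rectification).  Two complementary screens are applied trial-by-trial:
a Hann-tapered single-sided amplitude spectrum of the first second after
movement onset (kept below 60 Hz), and the autocorrelation of the
0.3–1 s post-onset segment, low-pass filtered below 60 Hz, whose first
local maximum at positive lag counts as an oscillation only when its
coefficient exceeds 0.3 and its lag falls within 25–350 ms (40–2.86 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignalTrace
from .filters import bandpass, lowpass_array

BANDS = {"torque": (3.0, 100.0), "emg": (3.0, 200.0)}
LAG_WINDOW_S = (0.025, 0.350)
MIN_COEFFICIENT = 0.3
FREQ_CAP_HZ = 60.0


@dataclass
class SpectralResult:
    """Amplitude spectrum and autocorrelation summary for one trial."""

    freqs: np.ndarray
    amplitude: np.ndarray
    autocorr_lags: Optional[np.ndarray] = None
    autocorr: Optional[np.ndarray] = None
    second_peak: Optional[tuple] = None       # (lag s, coefficient)


def lag_to_frequency(lag_s: float) -> float:
    """Oscillation frequency implied by an autocorrelation lag."""
    if lag_s <= 0:
        raise ValueError("lag must be positive")
    return 1.0 / lag_s


def preprocess(trace: SignalTrace, kind: str) -> SignalTrace:
    """Band-pass the signal for oscillation screening (no rectification)."""
    if kind not in BANDS:
        raise ValueError("kind must be 'torque' or 'emg'")
    return bandpass(trace, *BANDS[kind])


def amplitude_spectrum(trace: SignalTrace, onset: float,
                       seg_s: float = 1.0,
                       cap_hz: float = FREQ_CAP_HZ) -> SpectralResult:
    """Hann-tapered single-sided amplitude spectrum of 1 s post-onset."""
    if trace.t_end - onset < seg_s - 1e-9:
        raise ValueError("less than 1 s of data after movement onset")
    seg = trace.slice(onset, onset + seg_s).samples
    n = seg.size
    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(seg * win))
    # single-sided amplitude, compensated for the taper's coherent gain
    amp = 2.0 * spec / win.sum()
    amp[0] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.rate)
    keep = freqs < cap_hz
    return SpectralResult(freqs[keep], amp[keep])


def autocorr_second_peak(trace: SignalTrace, onset: float,
                         window: tuple = (0.3, 1.0),
                         lag_window: tuple = LAG_WINDOW_S,
                         min_r: float = MIN_COEFFICIENT
                         ) -> SpectralResult:
    """First qualifying autocorrelation peak of the post-onset segment.

    The first strict local maximum at positive lag is accepted only if
    its coefficient exceeds ``min_r`` and its lag lies inside
    ``lag_window``; otherwise the trial reports no oscillation.
    """
    if trace.t_end - onset < window[1] - 1e-9:
        raise ValueError("segment shorter than the autocorrelation window")
    seg = trace.slice(onset + window[0], onset + window[1]).samples
    x = seg - seg.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return SpectralResult(np.array([]), np.array([]))
    ac = np.correlate(x, x, mode="full")[x.size - 1:] / denom
    ac = lowpass_array(ac, FREQ_CAP_HZ, trace.rate)
    lags = np.arange(ac.size) / trace.rate
    peak = None
    for i in range(1, ac.size - 1):
        if ac[i] > ac[i - 1] and ac[i] >= ac[i + 1]:
            if lag_window[0] <= lags[i] <= lag_window[1] and ac[i] > min_r:
                peak = (float(lags[i]), float(ac[i]))
            break
    return SpectralResult(np.array([]), np.array([]), lags, ac, peak)


def compare_groups(spectra_small: pd.DataFrame, spectra_large: pd.DataFrame,
                   peaks_small: Optional[pd.DataFrame] = None,
                   peaks_large: Optional[pd.DataFrame] = None,
                   correction_size: Optional[int] = 60) -> dict:
    """Small- vs large-volley-trial comparison of spectra and peaks.

    Spectra frames hold one row per volley, one column per frequency; a
    per-frequency paired t-test with Bonferroni correction (default size
    60, configurable) is applied.  Peak frames hold columns ``lag`` and
    ``r``; group means are compared with two-tailed t-tests.
    """
    if len(spectra_small) < 2:
        raise ValueError("need at least 2 volleys per group")
    small = spectra_small.to_numpy(float)
    large = spectra_large.to_numpy(float)
    size = correction_size or small.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(large, small, axis=0)
    zero_var = np.nanstd(large - small, axis=0) == 0
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    spec = pd.DataFrame({
        "freq": spectra_small.columns.astype(float),
        "t": t, "p": p, "p_bonf": np.minimum(p * size, 1.0)})
    out = {"spectrum": spec}
    if peaks_small is not None and peaks_large is not None \
            and len(peaks_small) >= 2 and len(peaks_large) >= 2:
        for col in ("lag", "r"):
            with np.errstate(invalid="ignore", divide="ignore"):
                t2, p2 = stats.ttest_ind(peaks_large[col], peaks_small[col])
            out[col] = {"t": float(t2), "p": float(p2)}
    return out
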