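"""Antidromic-volley detection, area measurement and normalisation.

The volley evoked in the nerve-cuff neurogram by each intraspinal
microstimulation pulse is quantified from its stimulus-triggered average:
a significant volley continuously exceeds the baseline (−0.3 to −0.1 s
pre-stimulus) by two SDs for more than 0.2 ms with an onset latency under
5 ms.  Landmarks (onset, peak, trough, inflection, offset) are baseline
crossings of the average and are then applied unchanged to every
individual sweep; the per-sweep area sums the onset→inflection and
inflection→offset lobes with the negative lobe sign-inverted.  Areas are
z-scored against the Rest-epoch distribution of the same volley, so the
Rest mean maps to zero by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import Session, SignalTrace

log = logging.getLogger(__name__)

BASELINE_WINDOW = (-0.3, -0.1)   # s relative to stimulus
DEFAULT_WINDOW = (-0.3, 0.010)
DEFAULT_BLANK_MS = 0.5


@dataclass
class ADVTemplate:
    """Stimulus-aligned average volley with landmark times (ms post-stim)."""

    avg_waveform: SignalTrace
    baseline_mean: float
    baseline_sd: float
    n_sweeps: int
    blank_ms: float = DEFAULT_BLANK_MS
    significant: bool = False
    peak_t: Optional[float] = None
    trough_t: Optional[float] = None
    onset_t: Optional[float] = None
    inflection_t: Optional[float] = None
    offset_t: Optional[float] = None
    lobe_signs: tuple = ()
    latency: Optional[float] = None          # ms; = onset_t
    conduction_velocity: Optional[float] = None
    flags: list = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.avg_waveform.rate

    def _ms_index(self, t_ms: float) -> int:
        return self.avg_waveform.index_at(t_ms * 1e-3)


def extract_sweeps(neurogram: SignalTrace, stim_times: np.ndarray,
                   window: tuple = DEFAULT_WINDOW,
                   blank_ms: float = DEFAULT_BLANK_MS
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-aligned sweep matrix with artifacts blanked.

    The blanking zeroes ``[0, blank_ms]`` after *every* stimulus in the
    trace before alignment, so artifacts of neighbouring pulses cannot
    leak into another sweep's baseline.  Returns ``(matrix, kept)`` where
    ``kept`` indexes the stimuli whose window lies fully inside the trace.
    """
    rate = neurogram.rate
    x = neurogram.samples.copy()
    nb = max(int(round(blank_ms * 1e-3 * rate)), 1)
    for t in stim_times:
        i = int(round((t - neurogram.t0) * rate))
        if 0 <= i < x.size:
            x[i:i + nb] = 0.0
    pre = int(round(-window[0] * rate))
    post = int(round(window[1] * rate))
    idx0 = np.round((stim_times - neurogram.t0) * rate).astype(int)
    kept = np.flatnonzero((idx0 - pre >= 0) & (idx0 + post <= x.size))
    offsets = np.arange(-pre, post)
    matrix = x[idx0[kept][:, None] + offsets[None, :]]
    return matrix, kept


def average_sweeps(neurogram: SignalTrace, stim_times: np.ndarray,
                   window: tuple = DEFAULT_WINDOW,
                   blank_ms: float = DEFAULT_BLANK_MS,
                   min_stimuli: int = 50) -> ADVTemplate:
    """Stimulus-triggered grand average with baseline statistics."""
    stim_times = np.asarray(stim_times, float)
    if stim_times.size < min_stimuli:
        raise ValueError(f"need at least {min_stimuli} stimuli, "
                         f"got {stim_times.size}")
    if stim_times.size > 1:
        spacing = float(np.median(np.diff(np.sort(stim_times))))
        if spacing < window[1]:
            raise ValueError("stimulus spacing shorter than the "
                             "post-stimulus analysis window")
    matrix, kept = extract_sweeps(neurogram, stim_times, window, blank_ms)
    if matrix.shape[0] == 0:
        raise ValueError("no complete sweeps inside the trace")
    avg = matrix.mean(axis=0)
    trace = SignalTrace(avg, neurogram.rate, window[0], "adv_avg", "µV")
    b = trace.slice(*BASELINE_WINDOW).samples
    return ADVTemplate(trace, float(np.mean(b)), float(np.std(b)),
                       n_sweeps=matrix.shape[0], blank_ms=blank_ms)


def detect_significant_volley(template: ADVTemplate, n_sd: float = 2.0,
                              min_dur_ms: float = 0.2,
                              max_onset_ms: float = 5.0) -> bool:
    """Volley significance by the sustained baseline-excursion rule."""
    if template.baseline_sd == 0:
        raise ValueError("degenerate input: baseline SD is zero")
    tr = template.avg_waveform
    j0 = tr.index_at(template.blank_ms * 1e-3)
    x = np.abs(tr.samples[j0:] - template.baseline_mean)
    mask = x > n_sd * template.baseline_sd
    min_len = max(int(round(min_dur_ms * 1e-3 * tr.rate)), 1)
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        onset_ms = (tr.t0 + (j0 + s) / tr.rate) * 1e3
        if (e - s) > min_len and onset_ms < max_onset_ms:
            template.significant = True
            return True
    template.significant = False
    return False


def _crossings(x: np.ndarray) -> np.ndarray:
    """Indices i where the signal crosses zero between i-1 and i."""
    s = np.sign(x)
    hit = (s[1:] * s[:-1] < 0) | ((s[:-1] != 0) & (s[1:] == 0))
    return np.flatnonzero(hit) + 1


def _significant_runs(x: np.ndarray, thr: float, min_len: int) -> list:
    """(start, end) of runs with |x| > thr sustained for > min_len samples."""
    mask = np.abs(x) > thr
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    return [(s, e) for s, e in zip(starts, ends) if e - s > min_len]


def find_landmarks(template: ADVTemplate, n_sd: float = 2.0,
                   min_dur_ms: float = 0.2,
                   max_onset_ms: float = 5.0) -> ADVTemplate:
    """Peak/trough and baseline-crossing landmarks of a significant volley.

    Lobes are the sustained suprathreshold excursions (the same
    > ``n_sd``·SD for > ``min_dur_ms`` rule used for detection), so noise
    extremes cannot masquerade as a second lobe.  For monophasic volleys
    the inflection and offset coincide.  When several crossings separate
    the two lobes, the one closest to the midpoint of the peak and trough
    times is taken as the inflection.
    """
    tr = template.avg_waveform
    rate = tr.rate
    j0 = tr.index_at(template.blank_ms * 1e-3)
    x = tr.samples - template.baseline_mean
    post = x[j0:]
    t_ms = (tr.t0 + (j0 + np.arange(post.size)) / rate) * 1e3

    min_len = max(int(round(min_dur_ms * 1e-3 * rate)), 1)
    runs = [(s, e) for s, e in
            _significant_runs(post, n_sd * template.baseline_sd, min_len)
            if t_ms[s] < max_onset_ms or s == 0]
    if not runs:
        raise ValueError("no suprathreshold lobe; volley not significant")
    # first run = first lobe; an opposite-signed qualifying run directly
    # after it (within 2 ms) = second lobe
    lobes = []
    s0, e0 = runs[0]
    i0 = s0 + (np.argmin(post[s0:e0]) if post[s0:e0].mean() < 0
               else np.argmax(post[s0:e0]))
    sign0 = -1.0 if post[i0] < 0 else 1.0
    lobes.append((int(i0), sign0))
    for s, e in runs[1:]:
        if t_ms[s] - t_ms[e0] > 2.0:
            break
        i1 = s + (np.argmin(post[s:e]) if post[s:e].mean() < 0
                  else np.argmax(post[s:e]))
        sign1 = -1.0 if post[i1] < 0 else 1.0
        if sign1 != sign0:
            lobes.append((int(i1), sign1))
            break
        e0 = e
    i_min = min((i for i, sgn in lobes if sgn < 0), default=None)
    i_max = min((i for i, sgn in lobes if sgn > 0), default=None)
    first_i, first_sign = lobes[0]
    last_i, last_sign = lobes[-1]
    template.trough_t = float(t_ms[i_min]) if i_min is not None else None
    template.peak_t = float(t_ms[i_max]) if i_max is not None else None

    cross = _crossings(post)
    before = cross[cross <= first_i]
    template.onset_t = float(t_ms[before[-1]]) if before.size \
        else float(t_ms[0])
    after = cross[cross > last_i]
    if after.size:
        template.offset_t = float(t_ms[after[0]])
    else:
        template.offset_t = float(t_ms[-1])
        template.flags.append("offset_at_window_end")
    if len(lobes) == 2:
        between = cross[(cross > first_i) & (cross <= last_i)]
        if between.size:
            midpoint = 0.5 * (t_ms[first_i] + t_ms[last_i])
            template.inflection_t = float(
                t_ms[between[np.argmin(np.abs(t_ms[between] - midpoint))]])
        else:
            template.inflection_t = template.offset_t
            template.flags.append("no_interlobe_crossing")
        template.lobe_signs = (first_sign, last_sign)
    else:
        template.inflection_t = template.offset_t
        template.lobe_signs = (first_sign,)
    template.latency = template.onset_t
    return template


def measure_area(sweep: np.ndarray, template: ADVTemplate) -> float:
    """Volley area (µV·ms) of one sweep using the template's landmarks.

    The sweep must be aligned like the template's average window.  Bins
    are summed per lobe; the negative lobe's sum is sign-inverted so both
    lobes contribute positively.  The per-sweep baseline mean is
    subtracted, making the area invariant to DC offsets.
    """
    tr = template.avg_waveform
    if sweep.size < tr.samples.size:
        raise ValueError("sweep shorter than the template window")
    b0 = tr.index_at(BASELINE_WINDOW[0])
    b1 = tr.index_at(BASELINE_WINDOW[1])
    x = sweep - float(np.mean(sweep[b0:b1]))
    dt_ms = 1e3 / tr.rate
    i_on = template._ms_index(template.onset_t)
    i_off = template._ms_index(template.offset_t)
    if len(template.lobe_signs) == 2:
        i_inf = template._ms_index(template.inflection_t)
        s1 = float(np.sum(x[i_on:i_inf]))
        s2 = float(np.sum(x[i_inf:i_off]))
        area = (template.lobe_signs[0] * s1
                + template.lobe_signs[1] * s2) * dt_ms
    else:
        area = template.lobe_signs[0] * float(np.sum(x[i_on:i_off])) * dt_ms
    return area


def measure_sweeps(matrix: np.ndarray, template: ADVTemplate) -> np.ndarray:
    """Vectorised :func:`measure_area` over a sweep matrix."""
    return np.array([measure_area(row, template) for row in matrix])


def normalize_areas(areas: np.ndarray, rest_areas: np.ndarray,
                    min_rest: int = 20, ddof: int = 0) -> np.ndarray:
    """z-score areas against the Rest-epoch canonical distribution.

    Normality of the Rest distribution is checked (Shapiro-Wilk) and a
    deviation is logged; normalisation proceeds regardless.
    """
    rest_areas = np.asarray(rest_areas, float)
    if rest_areas.size < min_rest:
        raise ValueError(f"need at least {min_rest} Rest-epoch measures, "
                         f"got {rest_areas.size}")
    mu = float(np.mean(rest_areas))
    sd = float(np.std(rest_areas, ddof=ddof))
    if sd == 0:
        raise ValueError("Rest-area SD is zero; cannot z-score")
    if rest_areas.size >= 3:
        p = stats.shapiro(rest_areas[:5000]).pvalue
        if p < 0.05:
            log.warning("Rest-area distribution deviates from normality "
                        "(Shapiro-Wilk p=%.3g); z-scoring anyway", p)
    return (np.asarray(areas, float) - mu) / sd


def conduction_velocity(latency_ms: float, distance_m: float) -> float:
    """Conduction velocity (m/s) from volley latency and conduction distance."""
    if not (latency_ms > 0 and distance_m > 0):
        raise ValueError("latency and distance must be positive")
    return distance_m / (latency_ms * 1e-3)


def quantify_session(session: Session, segmentations: dict, outcomes: dict,
                     window: tuple = DEFAULT_WINDOW,
                     blank_ms: float = DEFAULT_BLANK_MS,
                     neurogram_label: str = "DR",
                     conduction_distance_m: Optional[float] = None,
                     min_stimuli: int = 50,
                     min_rest: int = 20) -> tuple[ADVTemplate, pd.DataFrame]:
    """Full per-session volley quantification.

    Averages all sweeps, detects and landmarks the volley, measures every
    stimulus, assigns each stimulus to its trial/epoch from the detected
    segmentation (half-open intervals), and z-scores areas against the
    Rest-epoch stimuli of perfect trials.
    """
    neuro = session.signals[neurogram_label]
    stim_times = session.stim_times()
    template = average_sweeps(neuro, stim_times, window, blank_ms,
                              min_stimuli=min_stimuli)
    if not detect_significant_volley(template):
        raise ValueError("no significant volley in this session")
    find_landmarks(template)
    if conduction_distance_m is not None and template.latency:
        template.conduction_velocity = conduction_velocity(
            template.latency, conduction_distance_m)

    matrix, kept = extract_sweeps(neuro, stim_times, window, blank_ms)
    areas = measure_sweeps(matrix, template)
    times = stim_times[kept]

    epoch = np.array([None] * times.size, dtype=object)
    trial_id = np.full(times.size, -1)
    direction = np.array([None] * times.size, dtype=object)
    perfect = np.zeros(times.size, dtype=bool)
    for tid, seg in segmentations.items():
        for name, a, b in seg.intervals():
            m = (times >= a) & (times < b)
            epoch[m] = name
            trial_id[m] = tid
            direction[m] = seg.direction
            perfect[m] = outcomes.get(tid) == "perfect"

    rest_mask = perfect & (epoch == "Rest")
    z = normalize_areas(areas, areas[rest_mask], min_rest=min_rest)
    df = pd.DataFrame({"stim_time": times, "raw_area": areas, "z_area": z,
                       "epoch": epoch, "trial_id": trial_id,
                       "direction": direction, "perfect": perfect})
    return template, df
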