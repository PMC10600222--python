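"""Peristimulus response probability of first-order spinal interneurons.

Spike times of a neuron receiving monosynaptic input from the stimulated
afferents are histogrammed around each stimulation pulse (0.5 ms bins),
separately per behavioural epoch.  Baseline statistics come from the
50 ms preceding stimulation; the response peak is the contiguous run of
bins around the maximal bin exceeding baseline + 2 SD, and its
above-baseline area divided by the stimulus count estimates the response
probability per stimulus.  Epochs are compared with exact two-tailed
binomial tests against the Rest-epoch probability (Bonferroni size 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

BIN_MS = 0.5
BASELINE_MS = 50.0
POST_MS = 10.0
#: Search window for the response peak, ms post-stimulus (monosynaptic
#: latency bounds).
PEAK_SEARCH_MS = (0.5, 5.0)
LOW_N = 20


@dataclass
class PSTHResult:
    """Per-epoch peristimulus histogram and response-peak measures."""

    epoch: str
    bin_edges: np.ndarray          # ms relative to stimulus
    counts: np.ndarray
    n_stimuli: int
    baseline_mean: float = 0.0     # counts per bin
    baseline_sd: float = 0.0
    peak_onset: Optional[float] = None    # ms
    peak_offset: Optional[float] = None
    peak_area: float = 0.0         # response probability per stimulus
    flags: list = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_psth(spikes: np.ndarray, stim_times: np.ndarray,
               stim_epochs: np.ndarray, bin_ms: float = BIN_MS,
               baseline_ms: float = BASELINE_MS,
               post_ms: float = POST_MS) -> dict[str, PSTHResult]:
    """Per-epoch peristimulus histograms with pre-stimulus baselines."""
    spikes = np.sort(np.asarray(spikes, float))
    stim_times = np.asarray(stim_times, float)
    stim_epochs = np.asarray(stim_epochs, dtype=object)
    edges = np.arange(-baseline_ms, post_ms + bin_ms / 2, bin_ms)
    n_base = int(round(baseline_ms / bin_ms))
    out = {}
    for epoch in pd.unique(stim_epochs):
        if epoch is None:
            continue
        st = stim_times[stim_epochs == epoch]
        counts = np.zeros(edges.size - 1)
        for t in st:
            rel = (spikes[(spikes >= t - baseline_ms * 1e-3)
                          & (spikes < t + post_ms * 1e-3)] - t) * 1e3
            counts += np.histogram(rel, bins=edges)[0]
        res = PSTHResult(str(epoch), edges, counts, st.size,
                         float(np.mean(counts[:n_base])),
                         float(np.std(counts[:n_base])))
        if st.size < LOW_N:
            res.flags.append("low_n")
        out[str(epoch)] = res
    return out


def peak_area(res: PSTHResult, n_sd: float = 2.0,
              search_ms: tuple = PEAK_SEARCH_MS) -> float:
    """Response probability from the significant peak of one histogram.

    The peak is the contiguous run of bins exceeding baseline + ``n_sd``
    SD around the maximal bin inside the search window; its summed
    above-baseline counts, divided by the stimulus count, estimate the
    probability of a response per stimulus.  No suprathreshold bin → 0.
    """
    centers = res.bin_centers
    inside = np.flatnonzero((centers >= search_ms[0])
                            & (centers <= search_ms[1]))
    if inside.size == 0 or res.n_stimuli == 0:
        res.peak_area = 0.0
        return 0.0
    thr = res.baseline_mean + n_sd * res.baseline_sd
    seg = res.counts[inside]
    if seg.max() <= thr:
        res.peak_area = 0.0
        return 0.0
    imax = inside[int(np.argmax(seg))]
    lo = imax
    while lo - 1 >= inside[0] and res.counts[lo - 1] > thr:
        lo -= 1
    hi = imax
    while hi + 1 <= inside[-1] and res.counts[hi + 1] > thr:
        hi += 1
    res.peak_onset = float(res.bin_edges[lo])
    res.peak_offset = float(res.bin_edges[hi + 1])
    area = float(np.sum(res.counts[lo:hi + 1] - res.baseline_mean))
    res.peak_area = max(area, 0.0) / res.n_stimuli
    return res.peak_area


def _common_window(results: dict[str, PSTHResult], n_sd: float,
                   search_ms: tuple) -> Optional[tuple[int, int]]:
    """Response window from the pooled histogram, shared by all epochs.

    Using one window keeps the per-epoch response counts comparable:
    per-epoch windows widen with stimulus count and would bias the
    contrasts between epochs of very different size.
    """
    first = next(iter(results.values()))
    pooled = np.zeros_like(first.counts)
    for res in results.values():
        if res.counts.size != pooled.size:
            raise ValueError("histograms have differing bin grids")
        pooled += res.counts
    n_base = int(round(-first.bin_edges[0] / (first.bin_edges[1]
                                              - first.bin_edges[0])))
    agg = PSTHResult("pooled", first.bin_edges, pooled,
                     sum(r.n_stimuli for r in results.values()),
                     float(np.mean(pooled[:n_base])),
                     float(np.std(pooled[:n_base])))
    if peak_area(agg, n_sd=n_sd, search_ms=search_ms) == 0.0:
        return None
    centers = agg.bin_centers
    lo = int(np.flatnonzero(np.isclose(agg.bin_edges[:-1],
                                       agg.peak_onset))[0])
    hi = int(np.flatnonzero(np.isclose(agg.bin_edges[1:],
                                       agg.peak_offset))[0])
    del centers
    return lo, hi


def epoch_response_tests(results: dict[str, PSTHResult],
                         control: str = "Rest",
                         correction_size: int = 4,
                         n_sd: float = 2.0,
                         search_ms: tuple = PEAK_SEARCH_MS) -> pd.DataFrame:
    """Exact binomial tests of each epoch's response count vs Rest.

    Responses are counted inside a single window detected from the
    pooled histogram, so epochs with different stimulus counts are
    compared on the same footing; each epoch's count is its
    above-baseline area in that window.  The Rest-epoch probability is
    the null parameter; tests are exact, two-tailed, with Bonferroni
    correction.
    """
    if control not in results:
        raise ValueError(f"control epoch {control!r} missing")
    window = _common_window(results, n_sd, search_ms)

    def response_count(res: PSTHResult) -> int:
        if window is None:
            return 0
        lo, hi = window
        excess = float(np.sum(res.counts[lo:hi + 1])
                       - res.baseline_mean * (hi + 1 - lo))
        return int(np.clip(round(excess), 0, res.n_stimuli))

    n0 = results[control].n_stimuli
    p0 = response_count(results[control]) / n0 if n0 else 0.0
    rows = []
    for epoch, res in results.items():
        if epoch == control:
            continue
        k = response_count(res)
        n = res.n_stimuli
        if p0 <= 0.0:
            p = 1.0 if k == 0 else 0.0
        elif p0 >= 1.0:
            p = 1.0 if k == n else 0.0
        else:
            p = stats.binomtest(k, n, p0).pvalue
        rows.append({"epoch": epoch, "k": k, "n": n,
                     "prob": k / n if n else 0.0, "rest_prob": p0,
                     "p": float(p),
                     "p_bonf": float(min(p * correction_size, 1.0)),
                     "low_n": "low_n" in res.flags})
    return pd.DataFrame(rows)
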