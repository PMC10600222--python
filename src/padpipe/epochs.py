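"""Post-hoc behavioural epoch definition and trial outcome classification.

Epochs are defined from the recorded torque and EMG rather than from the
task controller's log: Rest is the 0.8 s before the directional cue, Delay
runs from the cue to the onset of agonist EMG activity, Active Movement
(AM) from EMG onset to the offset of the dynamic torque change, Active
Hold (AH) from torque offset to the end cue, and Passive Movement (PM)
over the spring-driven return.  All intervals are half-open ``[start,
end)``.

Detectors follow standard-deviation-relative threshold rules (torque
derivative > k·SD of the rest-epoch derivative sustained ≥ 50 ms; EMG >
rest mean + 5 SD sustained ≥ 50 ms), so they are invariant to positive
amplitude rescaling and equivariant to time shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ConfigError, Session, SignalTrace, TrialRecord
from .filters import lowpass

log = logging.getLogger(__name__)

#: Sign of wrist torque for each instructed direction.
DIRECTION_SIGN = {"flexion": +1.0, "extension": -1.0}

REST_S = 0.8


@dataclass
class EpochSegmentation:
    """Epoch boundaries and detected landmarks for one trial."""

    trial_id: int
    direction: str
    rest: Optional[tuple] = None
    delay: Optional[tuple] = None
    am: Optional[tuple] = None
    ah: Optional[tuple] = None
    pm: Optional[tuple] = None
    torque_onset: Optional[float] = None
    torque_offset: Optional[float] = None
    emg_onset: Optional[float] = None
    emg_offset: Optional[float] = None
    pm_onset: Optional[float] = None
    pm_offset: Optional[float] = None
    flags: list = field(default_factory=list)

    def intervals(self) -> list[tuple]:
        out = []
        for name, iv in (("Rest", self.rest), ("Delay", self.delay),
                         ("AM", self.am), ("AH", self.ah), ("PM", self.pm)):
            if iv is not None:
                out.append((name, iv[0], iv[1]))
        return out

    @property
    def complete(self) -> bool:
        return all(iv is not None for iv in
                   (self.rest, self.delay, self.am, self.ah, self.pm))


def _sustained_crossing(mask: np.ndarray, min_len: int) -> Optional[int]:
    """First index opening a True run of at least ``min_len`` samples."""
    if not mask.any():
        return None
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            return int(s)
    return None


def detect_torque_onset(torque: SignalTrace, rest_window: tuple,
                        search_window: Optional[tuple] = None,
                        k: float = 3.0, d_min: float = 0.05,
                        floor_frac: float = 0.02) -> Optional[float]:
    """Movement onset from the derivative of <5 Hz low-pass-filtered torque.

    Returns the first time at which |d torque/dt| exceeds ``k`` SDs of the
    rest-window derivative and stays above for at least ``d_min`` seconds,
    or ``None``.  On noise-free input (rest SD = 0) a floor of
    ``floor_frac`` times the peak derivative in the search window keeps
    the threshold meaningful.
    """
    if rest_window[1] - rest_window[0] < 0.2:
        raise ValueError("rest window shorter than 0.2 s")
    f = lowpass(torque, 5.0)
    deriv = np.gradient(f.samples) * f.rate
    rest = f.slice(*rest_window)
    i0 = f.index_at(rest_window[0])
    rest_deriv = deriv[i0:i0 + len(rest)]
    sd = float(np.std(rest_deriv))
    if search_window is None:
        search_window = (rest_window[1], f.t_end)
    j0, j1 = f.index_at(search_window[0]), f.index_at(search_window[1])
    seg = np.abs(deriv[j0:j1])
    if seg.size == 0:
        return None
    thr = max(k * sd, floor_frac * float(seg.max()))
    if thr <= 0:
        return None
    hit = _sustained_crossing(seg > thr, max(int(d_min * f.rate), 1))
    if hit is None:
        return None
    return f.t0 + (j0 + hit) / f.rate


def detect_torque_offset(torque: SignalTrace, onset: float,
                         search_end: Optional[float] = None,
                         sign: Optional[float] = None,
                         zero_tol_frac: float = 0.02) -> Optional[float]:
    """Offset of the dynamic torque change.

    The first zero crossing of the movement-signed derivative after its
    peak; if the derivative never reaches zero inside the search window
    (noise-free asymptotic ramps), the first fall below ``zero_tol_frac``
    of the peak derivative is used.  ``None`` flags a trial with no
    plateau inside the window.
    """
    f = lowpass(torque, 5.0)
    deriv = np.gradient(f.samples) * f.rate
    if search_end is None:
        search_end = f.t_end
    j0, j1 = f.index_at(onset), f.index_at(search_end)
    if j1 <= j0 + 2:
        return None
    seg = deriv[j0:j1]
    if sign is None:
        sign = np.sign(seg[np.argmax(np.abs(seg))]) or 1.0
    d = sign * seg
    pk = int(np.argmax(d))
    after = d[pk:]
    cross = np.flatnonzero(after <= 0)
    if cross.size == 0:
        cross = np.flatnonzero(after <= zero_tol_frac * d[pk])
    if cross.size == 0:
        return None
    return f.t0 + (j0 + pk + int(cross[0])) / f.rate


def _smooth_rectified(emg: SignalTrace, cutoff: float) -> SignalTrace:
    rect = SignalTrace(np.abs(emg.samples), emg.rate, emg.t0,
                       emg.label, emg.units)
    return lowpass(rect, cutoff)


def detect_emg_onset(emg: SignalTrace, rest_window: tuple,
                     search_window: tuple, k: float = 5.0,
                     d_min: float = 0.05) -> Optional[float]:
    """Earliest EMG burst onset: rectified, 10 Hz low-passed trace
    exceeding rest mean + ``k``·SD continuously for ≥ ``d_min`` s."""
    if rest_window is None:
        raise ValueError("no Rest epoch available for EMG statistics")
    sm = _smooth_rectified(emg, 10.0)
    # amplitude statistics from the rectified, unsmoothed Rest trace:
    # a threshold this high is only held for >= d_min by genuine bursts
    rest = emg.slice(*rest_window)
    rect = np.abs(rest.samples)
    mu, sd = float(np.mean(rect)), float(np.std(rect))
    j0, j1 = sm.index_at(search_window[0]), sm.index_at(search_window[1])
    seg = sm.samples[j0:j1]
    thr = mu + k * sd
    hit = _sustained_crossing(seg > thr, max(int(d_min * sm.rate), 1))
    if hit is None:
        return None
    return sm.t0 + (j0 + hit) / sm.rate


def detect_emg_offset(emg: SignalTrace, torque_offset: float,
                      window: float = 0.3) -> Optional[float]:
    """EMG burst offset near movement offset.

    Among local maxima of the extra-smoothed (<3 Hz) rectified EMG within
    ``torque_offset ± window``, returns the one with the largest drop to
    its subsequent trough, or ``None`` when no local maximum exists.
    """
    sm = _smooth_rectified(emg, 3.0)
    j0 = sm.index_at(torque_offset - window)
    j1 = sm.index_at(torque_offset + window)
    x = sm.samples
    best, best_drop = None, -np.inf
    for i in range(max(j0, 1), min(j1, x.size - 1)):
        if x[i] >= x[i - 1] and x[i] > x[i + 1]:
            horizon = min(i + int(0.6 * sm.rate), x.size)
            trough = float(np.min(x[i:horizon]))
            drop = float(x[i]) - trough
            if drop > best_drop:
                best, best_drop = i, drop
    if best is None:
        return None
    return sm.t0 + best / sm.rate


def segment_epochs(trial: TrialRecord, torque: SignalTrace,
                   emg: SignalTrace, rest_s: float = REST_S,
                   **detector_kwargs) -> EpochSegmentation:
    """Detect all landmarks for one trial and assemble its epochs."""
    seg = EpochSegmentation(trial.trial_id, trial.direction)
    rest_window = (trial.cue_on - rest_s, trial.cue_on)
    seg.rest = rest_window
    if not np.isfinite(trial.go):
        return seg
    trial_end = (trial.reward_or_abort if np.isfinite(trial.reward_or_abort)
                 else min(trial.go + 3.0, torque.t_end))
    sign = DIRECTION_SIGN[trial.direction]

    seg.torque_onset = detect_torque_onset(
        torque, rest_window, (trial.go, min(trial.go + 1.5, trial_end)),
        **detector_kwargs)
    if seg.torque_onset is not None:
        seg.torque_offset = detect_torque_offset(
            torque, seg.torque_onset,
            min(seg.torque_onset + 1.5, trial_end), sign=sign)
        if seg.torque_offset is None:
            seg.flags.append("no_torque_plateau")
        search = (trial.cue_on, seg.torque_onset + 0.1)
        seg.emg_onset = detect_emg_onset(emg, rest_window, search)
        if seg.torque_offset is not None:
            seg.emg_offset = detect_emg_offset(emg, seg.torque_offset)
            if seg.emg_offset is None:
                seg.emg_offset = seg.torque_offset
                seg.flags.append("emg_offset_fallback")

    if seg.emg_onset is not None and seg.torque_offset is not None \
            and seg.emg_onset > seg.torque_offset:
        seg.flags.append("degenerate_am")
        return seg

    if seg.emg_onset is not None:
        seg.delay = (trial.cue_on, seg.emg_onset)
        if seg.torque_offset is not None:
            seg.am = (seg.emg_onset, seg.torque_offset)
            if np.isfinite(trial.end_cue) \
                    and trial.end_cue > seg.torque_offset:
                seg.ah = (seg.torque_offset, trial.end_cue)
                # passive return: opposite-signed movement after the end cue
                seg.pm_onset = detect_torque_onset(
                    torque, rest_window,
                    (trial.end_cue, min(trial.end_cue + 1.5, trial_end)),
                    **detector_kwargs)
                if seg.pm_onset is not None:
                    seg.pm_offset = detect_torque_offset(
                        torque, seg.pm_onset,
                        min(seg.pm_onset + 1.5, trial_end + 0.5), sign=-sign)
                    if seg.pm_offset is not None:
                        seg.pm = (seg.pm_onset, seg.pm_offset)
    return seg


def classify_trial(trial: TrialRecord, torque: SignalTrace,
                   target_torque: float, threshold_frac: float = 0.25,
                   rest_s: float = REST_S,
                   **detector_kwargs) -> str:
    """Outcome of one trial from its wrist torque.

    Rules: no detectable torque change after the Go signal → no_movement;
    first suprathreshold excursion in the direction opposite the
    instruction → wrong_direction; minimal torque between the peak-torque
    time and 1 s after movement onset below ``threshold_frac`` of the
    target → short_hold; otherwise success.
    """
    if not target_torque > 0:
        raise ConfigError("target torque must be > 0")
    if not 0.143 <= threshold_frac <= 0.375:
        raise ConfigError("short-hold threshold fraction outside the "
                          "14.3-37.5% band")
    rest_window = (trial.cue_on - rest_s, trial.cue_on)
    trial_end = (trial.reward_or_abort if np.isfinite(trial.reward_or_abort)
                 else min(trial.go + 3.0, torque.t_end))
    onset = detect_torque_onset(
        torque, rest_window, (trial.go, min(trial.go + 1.5, trial_end)),
        **detector_kwargs)
    if onset is None:
        return "no_movement"

    f = lowpass(torque, 5.0)
    sign = DIRECTION_SIGN[trial.direction]
    j0 = f.index_at(trial.go)
    j1 = f.index_at(min(trial.go + 2.0, trial_end))
    seg = f.samples[j0:j1]
    crossing = np.flatnonzero(np.abs(seg) >= threshold_frac * target_torque)
    if crossing.size == 0:
        # a derivative blip that never produces appreciable torque does
        # not count as a movement
        return "no_movement"
    if np.sign(seg[crossing[0]]) != sign:
        return "wrong_direction"

    k0 = f.index_at(onset)
    k1 = f.index_at(min(onset + 1.0, f.t_end))
    signed = sign * f.samples[k0:k1]
    if signed.size:
        pk = int(np.argmax(signed))
        if float(np.min(signed[pk:])) < threshold_frac * target_torque:
            return "short_hold"
    return "success"


def finalize_outcome(outcome: str, seg: EpochSegmentation) -> str:
    """Promote ``success`` to ``perfect`` when all five epochs completed."""
    if outcome == "success" and seg.complete and not seg.flags:
        return "perfect"
    return outcome


def select_agonists(session: Session,
                    rest_s: float = REST_S) -> dict[str, str]:
    """Representative agonist per direction: earliest mean EMG onset."""
    emg_labels = [lab for lab, tr in session.signals.items()
                  if tr.units == "µV" and lab.upper() not in ("DR",)]
    chosen = {}
    for direction in ("flexion", "extension"):
        best_label, best_onset = None, np.inf
        for lab in emg_labels:
            onsets = []
            for trial in session.trials:
                if trial.direction != direction or not np.isfinite(trial.go):
                    continue
                rest = (trial.cue_on - rest_s, trial.cue_on)
                t = detect_emg_onset(
                    session.signals[lab], rest,
                    (trial.cue_on, min(trial.go + 1.0,
                                       session.signals[lab].t_end)))
                if t is not None:
                    onsets.append(t - trial.cue_on)
            if onsets and np.mean(onsets) < best_onset:
                best_label, best_onset = lab, float(np.mean(onsets))
        if best_label is None and emg_labels:
            best_label = emg_labels[0]
            log.warning("no EMG onsets detected for %s; defaulting to %s",
                        direction, best_label)
        chosen[direction] = best_label
    return chosen


def segment_session(session: Session, target_torque: float = 1.0,
                    rest_s: float = REST_S,
                    agonists: Optional[dict] = None,
                    **detector_kwargs) -> tuple[dict, dict]:
    """Segment and classify every trial of a session.

    Returns ``(segmentations, outcomes)`` keyed by trial id; outcomes are
    final (``perfect`` where all five epochs completed).
    """
    torque = session.signals["torque"]
    if agonists is None:
        agonists = select_agonists(session, rest_s)
    segs, outcomes = {}, {}
    for trial in session.trials:
        emg = session.signals[agonists[trial.direction]]
        seg = segment_epochs(trial, torque, emg, rest_s, **detector_kwargs)
        out = classify_trial(trial, torque, target_torque,
                             rest_s=rest_s, **detector_kwargs)
        segs[trial.trial_id] = seg
        outcomes[trial.trial_id] = finalize_outcome(out, seg)
    return segs, outcomes
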