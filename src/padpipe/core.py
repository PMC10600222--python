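"""Shared domain types for multichannel behavioural-electrophysiology sessions.

A session bundles uniformly sampled signal traces (nerve-cuff neurogram,
multi-muscle EMG, wrist torque), the behavioural trial log, intraspinal
microstimulation event times, and optionally spike times of a recorded
spinal neuron.  All event times live on a single session clock in seconds
from recording start; epoch membership throughout the package uses
half-open intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

DIRECTIONS = ("flexion", "extension")
OUTCOMES = ("perfect", "success", "no_movement", "wrong_direction",
            "short_hold", "other_error")
#: Behavioural epochs in task order.  Rest is the normalisation anchor;
#: Delay/AM/AH/PM are the movement-related epochs that enter the
#: modulation analysis.
EPOCHS = ("Rest", "Delay", "AM", "AH", "PM")
MOVEMENT_EPOCHS = ("Delay", "AM", "AH", "PM")


class SchemaError(ValueError):
    """A session file does not follow the documented HDF5 schema."""


class ConfigError(ValueError):
    """A configuration value is impossible or inconsistent."""


@dataclass
class SignalTrace:
    """One uniformly sampled channel (neurogram, EMG or torque).

    Parameters
    ----------
    samples : ndarray
        Sample values; must be finite and non-empty.
    rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Session-clock time of the first sample, seconds.
    label : str
        Channel name, e.g. ``"DR"``, ``"ED23"``, ``"torque"``.
    units : str
        One of ``"N·m"``, ``"µV"``, ``"a.u."``.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    label: str = ""
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.samples).all():
            raise ValueError(f"non-finite samples in channel {self.label!r}")
        if not (self.rate > 0):
            raise ValueError("rate must be > 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n samples / rate)."""
        return self.samples.size / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_at(self, t: float) -> int:
        """Sample index whose time is nearest to ``t`` (clipped in range)."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.samples.size - 1)

    def slice(self, start: float, stop: float) -> "SignalTrace":
        """Sub-trace covering the half-open time interval ``[start, stop)``."""
        i0 = max(int(np.ceil((start - self.t0) * self.rate - 1e-9)), 0)
        i1 = min(int(np.ceil((stop - self.t0) * self.rate - 1e-9)),
                 self.samples.size)
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {stop}) of {self.label!r}")
        return replace(self, samples=self.samples[i0:i1],
                       t0=self.t0 + i0 / self.rate)


@dataclass
class TrialRecord:
    """One trial of the instructed-delay wrist flexion-extension task.

    Times are session-clock seconds; missing events (aborted trials) are
    ``nan``.  ``outcome`` is assigned exactly once per trial.
    """

    trial_id: int
    direction: str
    cue_on: float
    go: float
    end_cue: float
    reward_or_abort: float
    outcome: str = "other_error"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        seq = [t for t in (self.cue_on, self.go, self.end_cue)
               if np.isfinite(t)]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"trial {self.trial_id}: event times out of order")


@dataclass
class StimEvent:
    """A single intraspinal microstimulation pulse (10 Hz trains, ≤50 µA)."""

    time: float
    site_id: int = 0
    current: float = 30.0

    def __post_init__(self) -> None:
        if self.current > 50:
            raise ValueError("stimulation current above the 50 µA protocol cap")


@dataclass
class Session:
    """A complete recording session.

    ``signals`` maps channel label to :class:`SignalTrace`; ``trials`` and
    ``stims`` are the behavioural and stimulation logs; ``spikes`` holds
    spike times of one recorded spinal neuron when available.
    ``ground_truth`` is present only on synthetic sessions.
    """

    signals: dict[str, SignalTrace]
    trials: list[TrialRecord] = field(default_factory=list)
    stims: list[StimEvent] = field(default_factory=list)
    spikes: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)
    ground_truth: Optional["GroundTruth"] = None

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the session on the session clock."""
        starts = [s.t0 for s in self.signals.values()]
        ends = [s.t_end for s in self.signals.values()]
        return (min(starts), max(ends))

    def validate(self) -> None:
        """Check that all logged event times fall inside the session span."""
        lo, hi = self.span
        for ev in self.stims:
            if not (lo <= ev.time <= hi):
                raise ValueError(f"stim at {ev.time:.3f}s outside session span")
        for tr in self.trials:
            for t in (tr.cue_on, tr.go, tr.end_cue, tr.reward_or_abort):
                if np.isfinite(t) and not (lo <= t <= hi):
                    raise ValueError(
                        f"trial {tr.trial_id} event at {t:.3f}s outside span")

    def stim_times(self) -> np.ndarray:
        return np.asarray([ev.time for ev in self.stims], dtype=float)


@dataclass
class GroundTruth:
    """Known generating parameters of a synthetic session.

    ``epoch_gain`` maps ``(direction, epoch)`` to the multiplicative gain
    applied to volley amplitude for stimuli falling in that epoch;
    ``component_patterns`` lists ``(pattern, weight)`` pairs where the
    pattern is a vector over the movement epochs (Delay, AM, AH, PM) and
    the weight is this session's loading; ``trial_truth`` records the exact
    generated event times and injected outcome per trial.
    """

    epoch_gain: dict = field(default_factory=dict)
    component_patterns: list = field(default_factory=list)
    oscillation: Optional[tuple[float, float]] = None
    emg_onset_lead: float = 0.06
    response_prob: dict = field(default_factory=dict)
    seed: int = 0
    trial_truth: list[dict] = field(default_factory=list)
    adv: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, g in self.epoch_gain.items():
            if not g > 0:
                raise ValueError(f"epoch gain {key} must be > 0")
        for p in self.response_prob.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("response probabilities must lie in [0, 1]")

    def gain(self, direction: str, epoch: str) -> float:
        return self.epoch_gain.get((direction, epoch), 1.0)
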