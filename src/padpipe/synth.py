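"""Synthetic session generator with known ground truth.

Emulates the statistical structure the analysis assumes: an instructed-delay
wrist flexion-extension task against a spring load, 10 Hz intraspinal
microstimulation evoking biphasic antidromic volleys in a nerve-cuff
neurogram, EMG bursts leading torque onset, and epoch-dependent
multiplicative modulation of volley amplitude (the synthetic analogue of
primary-afferent-depolarisation modulation).  Everything is deterministic
given the seed; the injected parameters are returned as
:class:`~padpipe.core.GroundTruth` so every downstream stage can be checked
by parameter recovery.

The trial skeleton follows the task's stated timing: 0.8 s rest before the
cue, a 0.7 ± 0.2 s delay, 0.7–1 s active hold, and a spring-driven passive
return.  The torque ramp is a logistic rise (configurable timescale) and
the volley is a biphasic negative-then-positive raised-cosine, 1 ms total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (ConfigError, GroundTruth, Session, SignalTrace, StimEvent,
                   TrialRecord, MOVEMENT_EPOCHS)

AGONIST = {"extension": "ED23", "flexion": "FDS"}


@dataclass
class SimConfig:
    """Generator configuration.  Defaults are the study conditions.

    Timing parameters are seconds; amplitudes are µV (neurogram) or N·m
    (torque).  ``epoch_gain`` maps ``(direction, epoch)`` to a
    multiplicative volley-amplitude gain; ``component_patterns`` is a list
    of ``(pattern, weight)`` pairs adding ``weight * pattern[epoch]`` to
    the modulation of movement-epoch stimuli.
    """

    n_trials_per_direction: int = 20
    # behavioural timing
    rest_s: float = 0.8
    cue_flash_s: float = 0.3
    delay_mean_s: float = 0.7
    delay_jitter_s: float = 0.2
    reaction_s: float = 0.25
    ramp_tau_s: float = 0.15          # logistic 10-90% rise time
    hold_range_s: tuple = (0.7, 1.0)
    return_delay_s: float = 0.15
    reward_hold_s: float = 0.8
    intertrial_s: float = 0.5
    target_torque: float = 1.0
    # sampling rates (canonical defaults)
    neurogram_rate: float = 40_000.0
    emg_rate: float = 5_000.0
    torque_rate: float = 1_000.0
    # stimulation
    stim_rate_hz: float = 10.0
    stim_current_ua: float = 30.0
    site_id: int = 1
    # volley morphology and conduction
    adv_base_amp: float = 10.0
    adv_width_ms: float = 1.0
    conduction_distance_m: float = 0.13
    conduction_velocity_m_s: float = 65.0
    artifact_amp: float = 200.0
    artifact_ms: float = 0.3
    # noise levels
    neurogram_noise_sd: float = 1.0
    amp_noise_cv: float = 0.15
    torque_noise_sd: float = 0.01
    emg_rest_sd: float = 1.0
    emg_burst_gain: float = 8.0
    emg_hold_gain: float = 3.0
    emg_onset_lead_s: float = 0.06
    # modulation structure
    epoch_gain: dict = field(default_factory=dict)
    component_patterns: list = field(default_factory=list)
    oscillation: Optional[tuple] = None      # (freq Hz, torque amplitude)
    # injected error trials: class -> proportion per direction
    error_proportions: dict = field(default_factory=dict)
    # monosynaptically driven spinal neuron
    response_prob: Optional[dict] = None     # epoch -> probability
    response_latency_s: float = 0.0012
    response_jitter_s: float = 0.0001
    background_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.delay_mean_s - self.delay_jitter_s < 0:
            raise ConfigError("delay can become negative")
        if self.hold_range_s[0] > self.hold_range_s[1]:
            raise ConfigError("hold range reversed")
        if sum(self.error_proportions.values()) > 1.0 + 1e-9:
            raise ConfigError("error proportions exceed 1")
        if self.background_rate_hz < 0:
            raise ConfigError("background rate must be >= 0")
        for key, g in self.epoch_gain.items():
            if not g > 0:
                raise ConfigError(f"epoch gain {key} must be > 0")

    @property
    def ramp_duration_s(self) -> float:
        """Onset-to-plateau duration of the logistic torque ramp."""
        return 2.5 * self.ramp_tau_s

    @property
    def adv_latency_s(self) -> float:
        return self.conduction_distance_m / self.conduction_velocity_m_s


def adv_kernel(rate: float, width_ms: float = 1.0,
               amp: float = 1.0) -> np.ndarray:
    """Biphasic volley template: raised-cosine negative then positive lobe."""
    n = max(int(round(width_ms * 1e-3 * rate)), 4)
    half = n // 2
    t1 = np.arange(half) / half
    t2 = np.arange(n - half) / (n - half)
    return amp * np.concatenate([-np.sin(np.pi * t1) ** 2,
                                 np.sin(np.pi * t2) ** 2])


def _logistic(t: np.ndarray, mid: float, sc: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip((t - mid) / sc, -60, 60)))


def _edge_box(t: np.ndarray, start: float, stop: float,
              edge: float = 0.05) -> np.ndarray:
    """Unit box over [start, stop] with raised-cosine edges of width ``edge``."""
    y = np.zeros_like(t)
    rise = (t >= start) & (t < start + edge)
    y[rise] = np.sin(0.5 * np.pi * (t[rise] - start) / edge) ** 2
    y[(t >= start + edge) & (t <= stop - edge)] = 1.0
    fall = (t > stop - edge) & (t <= stop)
    y[fall] = np.sin(0.5 * np.pi * (stop - t[fall]) / edge) ** 2
    return y


def _schedule_trials(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Lay out trial-by-trial event times and injected outcomes."""
    n = cfg.n_trials_per_direction
    directions = ["flexion"] * n + ["extension"] * n
    directions = [directions[i] for i in rng.permutation(2 * n)]

    # deterministic error counts per direction, assigned to random trials
    outcome_by_dir = {}
    for d in ("flexion", "extension"):
        labels = ["perfect"] * n
        idx = list(rng.permutation(n))
        for err, prop in cfg.error_proportions.items():
            k = int(round(prop * n))
            for _ in range(k):
                labels[idx.pop()] = err
        outcome_by_dir[d] = labels

    used = {"flexion": 0, "extension": 0}
    trials = []
    t = cfg.intertrial_s
    for tid, d in enumerate(directions):
        outcome = outcome_by_dir[d][used[d]]
        used[d] += 1
        cue_on = t + cfg.rest_s
        delay = cfg.delay_mean_s + cfg.delay_jitter_s * rng.uniform(-1, 1)
        go = cue_on + cfg.cue_flash_s + delay
        tr = {"trial_id": tid, "direction": d, "outcome": outcome,
              "cue_on": cue_on, "go": go, "emg_onset": None,
              "torque_onset": None, "torque_offset": None, "end_cue": None,
              "pm_onset": None, "pm_offset": None, "reward_or_abort": None}
        if outcome == "no_movement":
            tr["reward_or_abort"] = go + 0.35
        elif outcome == "wrong_direction":
            onset = go + cfg.reaction_s
            tr["torque_onset"] = onset
            tr["emg_onset"] = onset - cfg.emg_onset_lead_s
            tr["reward_or_abort"] = onset + 0.3 + cfg.ramp_duration_s
        elif outcome == "short_hold":
            onset = go + cfg.reaction_s
            offset = onset + cfg.ramp_duration_s
            tr["torque_onset"] = onset
            tr["emg_onset"] = onset - cfg.emg_onset_lead_s
            tr["torque_offset"] = offset
            tr["reward_or_abort"] = offset + 0.25 + cfg.ramp_duration_s
        else:  # perfect
            onset = go + cfg.reaction_s
            offset = onset + cfg.ramp_duration_s
            hold = rng.uniform(*cfg.hold_range_s)
            end_cue = offset + hold
            pm_onset = end_cue + cfg.return_delay_s
            pm_offset = pm_onset + cfg.ramp_duration_s
            tr.update(emg_onset=onset - cfg.emg_onset_lead_s,
                      torque_onset=onset, torque_offset=offset,
                      end_cue=end_cue, pm_onset=pm_onset,
                      pm_offset=pm_offset,
                      reward_or_abort=pm_offset + cfg.reward_hold_s)
        trials.append(tr)
        t = tr["reward_or_abort"] + cfg.intertrial_s
    return trials


def epoch_intervals(trial: dict, rest_s: float = 0.8) -> list[tuple]:
    """Half-open ``(epoch, start, stop)`` intervals for one trial-truth dict."""
    out = [("Rest", trial["cue_on"] - rest_s, trial["cue_on"])]
    if trial["outcome"] != "perfect":
        return out
    out += [("Delay", trial["cue_on"], trial["emg_onset"]),
            ("AM", trial["emg_onset"], trial["torque_offset"]),
            ("AH", trial["torque_offset"], trial["end_cue"]),
            ("PM", trial["pm_onset"], trial["pm_offset"])]
    return out


def label_stim_epochs(stim_times: np.ndarray,
                      trial_truth: list[dict],
                      rest_s: float = 0.8) -> pd.DataFrame:
    """Assign each stimulus to (trial, direction, epoch) by half-open rule."""
    epoch = np.array([None] * stim_times.size, dtype=object)
    trial_id = np.full(stim_times.size, -1)
    direction = np.array([None] * stim_times.size, dtype=object)
    for tr in trial_truth:
        for name, a, b in epoch_intervals(tr, rest_s):
            m = (stim_times >= a) & (stim_times < b)
            epoch[m] = name
            trial_id[m] = tr["trial_id"]
            direction[m] = tr["direction"]
    return pd.DataFrame({"stim_time": stim_times, "epoch": epoch,
                         "trial_id": trial_id, "direction": direction})


def _torque_signal(cfg: SimConfig, trials: list[dict], n: int,
                   rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / cfg.torque_rate
    y = np.zeros(n)
    sc = cfg.ramp_tau_s / 4.39          # logistic scale for 10-90% rise
    for tr in trials:
        sign = +1.0 if tr["direction"] == "flexion" else -1.0
        amp = sign * cfg.target_torque
        if tr["outcome"] == "no_movement":
            continue
        if tr["outcome"] == "wrong_direction":
            onset = tr["torque_onset"]
            mid = onset + 0.5 * cfg.ramp_duration_s
            seg = (t >= onset - 0.2) & (t <= tr["reward_or_abort"] + 0.5)
            rise = _logistic(t[seg], mid, sc)
            fall = _logistic(t[seg], mid + 0.3 + cfg.ramp_duration_s, sc)
            y[seg] += -0.75 * amp * (rise - fall)
            continue
        onset = tr["torque_onset"]
        mid = onset + 0.5 * cfg.ramp_duration_s
        if tr["outcome"] == "short_hold":
            release_mid = (tr["torque_offset"] + 0.25
                           + 0.5 * cfg.ramp_duration_s)
            seg = (t >= onset - 0.3) & (t <= tr["reward_or_abort"] + 0.5)
            y[seg] += amp * (_logistic(t[seg], mid, sc)
                             - _logistic(t[seg], release_mid, sc))
            continue
        # perfect: rise, hold, passive return mirroring the rise
        pm_mid = tr["pm_onset"] + 0.5 * cfg.ramp_duration_s
        seg = (t >= onset - 0.3) & (t <= tr["pm_offset"] + 0.5)
        y[seg] += amp * (_logistic(t[seg], mid, sc)
                         - _logistic(t[seg], pm_mid, sc))
        if cfg.oscillation is not None:
            f, a = cfg.oscillation
            osc = (t >= onset) & (t < tr["end_cue"])
            y[osc] += a * np.sin(2 * np.pi * f * (t[osc] - onset))
    if cfg.torque_noise_sd > 0:
        y += rng.normal(0, cfg.torque_noise_sd, n)
    return y


def _emg_signal(cfg: SimConfig, trials: list[dict], muscle_dir: str,
                n: int, rng: np.random.Generator) -> np.ndarray:
    """Noise amplitude-modulated by phasic + tonic burst envelopes."""
    t = np.arange(n) / cfg.emg_rate
    env = np.zeros(n)
    for tr in trials:
        if tr["direction"] != muscle_dir or tr["emg_onset"] is None:
            continue
        phasic_end = tr["torque_offset"]
        if phasic_end is None:  # wrong_direction trials: short burst
            phasic_end = tr["emg_onset"] + cfg.ramp_duration_s
        env += (cfg.emg_burst_gain - 1.0) * _edge_box(
            t, tr["emg_onset"], phasic_end)
        if tr["outcome"] in ("perfect",):
            env += (cfg.emg_hold_gain - 1.0) * _edge_box(
                t, phasic_end, tr["end_cue"])
        elif tr["outcome"] == "short_hold":
            env += (cfg.emg_hold_gain - 1.0) * _edge_box(
                t, phasic_end, phasic_end + 0.25)
    return cfg.emg_rest_sd * (1.0 + env) * rng.standard_normal(n)


def _neurogram(cfg: SimConfig, stim_df: pd.DataFrame, gt: GroundTruth,
               n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Noise + stimulus artifacts + modulated biphasic volleys.

    Returns the signal and the per-stimulus true volley amplitudes.
    """
    rate = cfg.neurogram_rate
    y = (rng.standard_normal(n) * cfg.neurogram_noise_sd
         if cfg.neurogram_noise_sd > 0 else np.zeros(n))

    movement_idx = {e: i for i, e in enumerate(MOVEMENT_EPOCHS)}
    amps = np.empty(len(stim_df))
    for i, (_, row) in enumerate(stim_df.iterrows()):
        e = row["epoch"]
        gain = 1.0
        if e is not None and e != "Rest":
            gain = gt.gain(row["direction"], e)
            if e in movement_idx:
                comp = 1.0
                for pattern, w in gt.component_patterns:
                    comp += w * float(np.asarray(pattern)[movement_idx[e]])
                gain *= comp
        noise = (1.0 + cfg.amp_noise_cv * rng.standard_normal()
                 if cfg.amp_noise_cv > 0 else 1.0)
        amps[i] = max(cfg.adv_base_amp * gain * noise, 0.0)

    stim_idx = np.round(stim_df["stim_time"].to_numpy() * rate).astype(int)
    # saturating stimulus artifact at t=0 (exercises blanking logic)
    na = max(int(round(cfg.artifact_ms * 1e-3 * rate)), 2)
    art = cfg.artifact_amp * (1.0 - np.arange(na) / na)
    kern = adv_kernel(rate, cfg.adv_width_ms)
    lat = int(round(cfg.adv_latency_s * rate))
    for i0, a in zip(stim_idx, amps):
        if i0 + na < n:
            y[i0:i0 + na] += art
        j0 = i0 + lat
        if j0 + kern.size < n:
            y[j0:j0 + kern.size] += a * kern
    return y, amps


def generate_spike_train(cfg: SimConfig, stim_df: pd.DataFrame,
                         duration: float, seed: int) -> np.ndarray:
    """Spike times of a first-order interneuron driven by the stimuli.

    Each stimulus is independently followed by one spike at the
    monosynaptic latency with its epoch's response probability; background
    activity is homogeneous Poisson at ``background_rate_hz``.
    """
    if cfg.background_rate_hz < 0:
        raise ConfigError("background rate must be >= 0")
    rng = np.random.default_rng(seed)
    probs = cfg.response_prob or {}
    spikes = []
    for _, row in stim_df.iterrows():
        p = probs.get(row["epoch"], 0.0) if row["epoch"] is not None else 0.0
        if p > 0 and rng.random() < p:
            spikes.append(row["stim_time"] + cfg.response_latency_s
                          + cfg.response_jitter_s * rng.standard_normal())
    n_bg = rng.poisson(cfg.background_rate_hz * duration)
    spikes.extend(rng.uniform(0, duration, n_bg))
    return np.sort(np.asarray(spikes))


def generate_session(cfg: SimConfig, seed: int) -> Session:
    """Generate a complete synthetic session with ground truth attached."""
    rng = np.random.default_rng(seed)
    trials = _schedule_trials(cfg, rng)
    duration = trials[-1]["reward_or_abort"] + cfg.intertrial_s

    gt = GroundTruth(
        epoch_gain=dict(cfg.epoch_gain),
        component_patterns=[(np.asarray(p, float), float(w))
                            for p, w in cfg.component_patterns],
        oscillation=cfg.oscillation,
        emg_onset_lead=cfg.emg_onset_lead_s,
        response_prob=dict(cfg.response_prob or {}),
        seed=seed,
        trial_truth=trials,
        adv={"latency_s": cfg.adv_latency_s,
             "conduction_velocity_m_s": cfg.conduction_velocity_m_s,
             "conduction_distance_m": cfg.conduction_distance_m,
             "base_amp": cfg.adv_base_amp,
             "width_ms": cfg.adv_width_ms},
    )

    stim_times = np.arange(0.05, duration - 0.05, 1.0 / cfg.stim_rate_hz)
    stim_df = label_stim_epochs(stim_times, trials, cfg.rest_s)

    n_t = int(round(duration * cfg.torque_rate))
    n_e = int(round(duration * cfg.emg_rate))
    n_n = int(round(duration * cfg.neurogram_rate))
    torque = _torque_signal(cfg, trials, n_t, rng)
    emg_ext = _emg_signal(cfg, trials, "extension", n_e, rng)
    emg_flex = _emg_signal(cfg, trials, "flexion", n_e, rng)
    neuro, amps = _neurogram(cfg, stim_df, gt, n_n, rng)
    gt.adv["stim_amps"] = [float(a) for a in amps]

    signals = {
        "torque": SignalTrace(torque, cfg.torque_rate, 0.0, "torque", "N·m"),
        "ED23": SignalTrace(emg_ext, cfg.emg_rate, 0.0, "ED23", "µV"),
        "FDS": SignalTrace(emg_flex, cfg.emg_rate, 0.0, "FDS", "µV"),
        "DR": SignalTrace(neuro, cfg.neurogram_rate, 0.0, "DR", "µV"),
    }
    trial_records = [
        TrialRecord(tr["trial_id"], tr["direction"], tr["cue_on"], tr["go"],
                    tr["end_cue"] if tr["end_cue"] is not None else np.nan,
                    tr["reward_or_abort"], tr["outcome"])
        for tr in trials]
    stims = [StimEvent(float(t), cfg.site_id, cfg.stim_current_ua)
             for t in stim_times]

    spikes = None
    if cfg.response_prob is not None:
        spikes = generate_spike_train(cfg, stim_df, duration,
                                      seed=int(rng.integers(2 ** 31)))
    return Session(signals, trial_records, stims, spikes,
                   {"subject": "synthetic", "seed": seed}, gt)


# ---------------------------------------------------------------------------
# population-level generators (many volleys, compiled-measures scale)

def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


#: Canonical latent patterns over (Delay, AM, AH, PM): a transient
#: disinhibition peaking in the active-movement epoch, and a sustained
#: facilitation spanning the trial.  The sustained pattern is
#: orthogonalised against the transient so the pair is exactly orthogonal.
AM_TRANSIENT_PATTERN = _unit([0.15, 1.0, 0.2, 0.1])
_sustained_raw = np.array([0.8, 0.0, 1.0, 0.6])
FLEXION_SUSTAINED_PATTERN = _unit(
    _sustained_raw - (_sustained_raw @ AM_TRANSIENT_PATTERN)
    * AM_TRANSIENT_PATTERN)


@dataclass
class PopulationComponent:
    """One latent modulation pattern shared across a volley population.

    ``pattern`` is a vector over the movement epochs (Delay, AM, AH, PM);
    per-volley loadings are drawn from a (non-Gaussian) exponential with
    the given direction-specific scales, so independent-component recovery
    is well posed.
    """

    pattern: np.ndarray
    flexion_scale: float = 1.0
    extension_scale: float = 1.0

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        nrm = np.linalg.norm(self.pattern)
        if nrm == 0:
            raise ConfigError("zero component pattern")
        self.pattern = self.pattern / nrm


def generate_profile_population(n_adv: int,
                                components: list[PopulationComponent],
                                noise_sd: float,
                                seed: int) -> tuple[pd.DataFrame, dict]:
    """Per-volley epoch-mean profiles for a population of ``n_adv`` volleys.

    Emulates compiled z-scored epoch means: each (volley, direction) row is
    a weighted sum of the latent patterns plus Gaussian noise.  Rows are
    returned flexion block first, matching the decomposition convention.
    """
    rng = np.random.default_rng(seed)
    rows = []
    weights = np.zeros((2 * n_adv, len(components)))
    for bi, direction in enumerate(("flexion", "extension")):
        for i in range(n_adv):
            r = bi * n_adv + i
            prof = np.zeros(4)
            for k, comp in enumerate(components):
                scale = (comp.flexion_scale if direction == "flexion"
                         else comp.extension_scale)
                w = rng.exponential(scale) if scale > 0 else 0.0
                weights[r, k] = w
                prof += w * comp.pattern
            prof += rng.normal(0, noise_sd, 4)
            rows.append({"adv_id": i, "direction": direction,
                         "Delay": prof[0], "AM": prof[1],
                         "AH": prof[2], "PM": prof[3]})
    truth = {"patterns": np.stack([c.pattern for c in components]),
             "weights": weights}
    return pd.DataFrame(rows), truth


def generate_null_epoch_means(n_adv: int, seed: int) -> pd.DataFrame:
    """Null population: every epoch cell i.i.d. standard normal."""
    rng = np.random.default_rng(seed)
    rows = []
    for direction in ("flexion", "extension"):
        vals = rng.standard_normal((n_adv, 4))
        for i in range(n_adv):
            rows.append({"adv_id": i, "direction": direction,
                         "Delay": vals[i, 0], "AM": vals[i, 1],
                         "AH": vals[i, 2], "PM": vals[i, 3]})
    return pd.DataFrame(rows)
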