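"""Generator: determinism, injected structure, and spike statistics."""

import numpy as np
import pytest

from padpipe import (ConfigError, SimConfig, generate_session,
                     generate_spike_train, label_stim_epochs)
from padpipe.synth import _schedule_trials

from conftest import make_config


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = make_config(n_trials_per_direction=3)
        a = generate_session(cfg, seed=5)
        b = generate_session(cfg, seed=5)
        for label in a.signals:
            assert np.array_equal(a.signals[label].samples,
                                  b.signals[label].samples)
        assert [t.outcome for t in a.trials] == [t.outcome for t in b.trials]

    def test_seed_changes_output(self):
        cfg = make_config(n_trials_per_direction=3)
        a = generate_session(cfg, seed=5)
        b = generate_session(cfg, seed=6)
        assert not np.array_equal(a.signals["DR"].samples,
                                  b.signals["DR"].samples)


class TestSchedule:
    def test_outcome_proportions_exact(self):
        cfg = make_config(n_trials_per_direction=10,
                          error_proportions={"no_movement": 0.2,
                                             "short_hold": 0.1})
        s = generate_session(cfg, seed=2)
        outs = [t.outcome for t in s.trials]
        assert outs.count("no_movement") == 4      # 2 per direction
        assert outs.count("short_hold") == 2
        assert outs.count("perfect") == 14
        for d in ("flexion", "extension"):
            assert sum(t.direction == d for t in s.trials) == 10

    def test_impossible_timing_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(delay_mean_s=0.1, delay_jitter_s=0.3)
        with pytest.raises(ConfigError):
            SimConfig(hold_range_s=(1.0, 0.7))
        with pytest.raises(ConfigError):
            SimConfig(epoch_gain={("flexion", "AM"): 0.0})

    def test_event_times_inside_span(self, gain_session):
        gain_session.validate()

    def test_stim_spacing_matches_rate(self, gain_session):
        d = np.diff(gain_session.stim_times())
        assert np.allclose(d, 0.1, atol=1e-9)


class TestInjectedModulation:
    def test_noise_free_amps_identical(self):
        cfg = make_config(n_trials_per_direction=3, amp_noise_cv=0.0,
                          neurogram_noise_sd=0.0)
        s = generate_session(cfg, seed=1)
        amps = np.asarray(s.ground_truth.adv["stim_amps"])
        assert np.allclose(amps, amps[0])

    def test_gain_recovered_by_direct_averaging(self):
        # oracle: mean true amplitude per epoch over the generated sweeps
        cfg = make_config(n_trials_per_direction=12,
                          epoch_gain={("extension", "AM"): 0.7})
        s = generate_session(cfg, seed=4)
        labels = label_stim_epochs(s.stim_times(),
                                   s.ground_truth.trial_truth)
        amps = np.asarray(s.ground_truth.adv["stim_amps"])
        am = amps[(labels.epoch == "AM")
                  & (labels.direction == "extension")]
        rest = amps[(labels.epoch == "Rest")
                    & (labels.direction == "extension")]
        ratio = am.mean() / rest.mean()
        mc = 2 * cfg.amp_noise_cv * np.sqrt(1 / am.size + 1 / rest.size)
        assert ratio == pytest.approx(0.7, abs=3 * 0.7 * mc + 0.02)

    def test_component_pattern_scales_movement_epochs(self):
        pattern = np.array([0.0, 1.0, 0.0, 0.0])
        cfg = make_config(n_trials_per_direction=6, amp_noise_cv=0.0,
                          neurogram_noise_sd=0.0,
                          component_patterns=[(pattern, 0.5)])
        s = generate_session(cfg, seed=9)
        labels = label_stim_epochs(s.stim_times(),
                                   s.ground_truth.trial_truth)
        amps = np.asarray(s.ground_truth.adv["stim_amps"])
        am = amps[labels.epoch == "AM"].mean()
        rest = amps[labels.epoch == "Rest"].mean()
        assert am / rest == pytest.approx(1.5, rel=1e-9)

    def test_emg_onset_leads_torque_onset(self, gain_session):
        for tr in gain_session.ground_truth.trial_truth:
            if tr["outcome"] == "perfect":
                lead = tr["torque_onset"] - tr["emg_onset"]
                assert lead == pytest.approx(
                    gain_session.ground_truth.emg_onset_lead)


class TestSpikeTrain:
    @staticmethod
    def _stim_frame(cfg, seed):
        s = generate_session(cfg, seed=seed)
        return s, label_stim_epochs(s.stim_times(),
                                    s.ground_truth.trial_truth)

    def test_certain_response_always_present(self):
        cfg = make_config(n_trials_per_direction=4,
                          response_prob={"Rest": 1.0},
                          background_rate_hz=0.0)
        s, labels = self._stim_frame(cfg, 3)
        spikes = generate_spike_train(cfg, labels, s.span[1], seed=0)
        rest = labels[labels.epoch == "Rest"]
        for t in rest.stim_time:
            assert np.any((spikes > t) & (spikes < t + 0.003))

    def test_probability_recovered_within_binomial_error(self):
        p_true = 0.8
        cfg = make_config(n_trials_per_direction=20,
                          response_prob={"Rest": p_true},
                          background_rate_hz=0.0)
        s, labels = self._stim_frame(cfg, 5)
        spikes = generate_spike_train(cfg, labels, s.span[1], seed=1)
        rest = labels[labels.epoch == "Rest"].stim_time.to_numpy()
        hits = sum(np.any((spikes > t) & (spikes < t + 0.003))
                   for t in rest)
        se = np.sqrt(p_true * (1 - p_true) / rest.size)
        assert hits / rest.size == pytest.approx(p_true, abs=2.5 * se)

    def test_negative_background_rate_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(background_rate_hz=-1.0)


class TestScheduleInternals:
    def test_perfect_trials_have_all_epochs(self):
        cfg = make_config(n_trials_per_direction=4)
        trials = _schedule_trials(cfg, np.random.default_rng(0))
        for tr in trials:
            assert tr["cue_on"] < tr["go"] < tr["torque_onset"]
            assert tr["emg_onset"] < tr["torque_onset"] < tr["torque_offset"]
            assert tr["torque_offset"] < tr["end_cue"] < tr["pm_onset"]
            hold = tr["end_cue"] - tr["torque_offset"]
            assert cfg.hold_range_s[0] - 1e-9 <= hold \
                   <= cfg.hold_range_s[1] + 1e-9
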