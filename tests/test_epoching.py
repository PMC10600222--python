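"""Onset/offset detectors, epoch assembly and outcome classification."""

import numpy as np
import pytest

from padpipe import (ConfigError, SignalTrace, TrialRecord, classify_trial,
                     detect_emg_onset, detect_emg_offset,
                     detect_torque_onset, detect_torque_offset,
                     generate_session, segment_session)

from conftest import make_config


def logistic_ramp(rate=500.0, t_on=2.0, tau=0.15, dur=6.0, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    sc = tau / 4.39
    y = amp / (1.0 + np.exp(-np.clip((t - (t_on + 1.25 * tau)) / sc,
                                     -60, 60)))
    return SignalTrace(y, rate, 0.0, "torque", "N·m")


class TestTorqueOnset:
    def test_constant_torque_no_onset(self):
        tr = SignalTrace(np.full(3000, 0.7), 500.0)
        assert detect_torque_onset(tr, (0.5, 1.3), (1.5, 5.0)) is None

    def test_noise_free_logistic_matches_analytic_oracle(self):
        # oracle: first time the analytic logistic derivative exceeds the
        # detector's floor (2% of peak); agreement is limited by the 5 Hz
        # zero-phase smoothing (step response spread ~40 ms)
        t_on, tau = 2.0, 0.15
        tr = logistic_ramp(t_on=t_on, tau=tau)
        sc = tau / 4.39
        mid = t_on + 1.25 * tau
        tt = np.arange(int(1.8 * tr.rate), int(4.0 * tr.rate)) / tr.rate
        deriv = np.exp(-(tt - mid) / sc) / sc \
            / (1 + np.exp(-(tt - mid) / sc)) ** 2
        expected = tt[np.flatnonzero(deriv > 0.02 * deriv.max())[0]]
        got = detect_torque_onset(tr, (1.0, 1.8), (1.8, 4.0))
        assert got == pytest.approx(expected, abs=0.05)
        assert got == pytest.approx(t_on, abs=0.05)

    def test_short_rest_window_rejected(self):
        tr = logistic_ramp()
        with pytest.raises(ValueError):
            detect_torque_onset(tr, (1.0, 1.1))

    def test_amplitude_scale_invariance(self):
        a = logistic_ramp(amp=1.0)
        b = logistic_ramp(amp=7.3)
        ta = detect_torque_onset(a, (1.0, 1.8), (1.8, 4.0))
        tb = detect_torque_onset(b, (1.0, 1.8), (1.8, 4.0))
        assert ta == pytest.approx(tb, abs=1 / a.rate)

    def test_time_shift_equivariance(self):
        a = logistic_ramp(t_on=2.0)
        b = logistic_ramp(t_on=3.0)
        ta = detect_torque_onset(a, (1.0, 1.8), (1.8, 4.0))
        tb = detect_torque_onset(b, (2.0, 2.8), (2.8, 5.0))
        assert tb - ta == pytest.approx(1.0, abs=0.01)


class TestTorqueOffset:
    def test_logistic_plateau(self):
        tr = logistic_ramp(t_on=2.0, tau=0.15)
        off = detect_torque_offset(tr, 2.0, search_end=5.0)
        # plateau reached ~2.5 tau after onset (analytic logistic)
        assert off == pytest.approx(2.0 + 2.5 * 0.15, abs=0.1)

    def test_monotone_ramp_flagged(self):
        rate = 500.0
        y = np.linspace(0, 1, int(2 * rate))     # never reaches a plateau
        tr = SignalTrace(y, rate)
        assert detect_torque_offset(tr, 0.5, search_end=1.9) is None


class TestEmgDetectors:
    @staticmethod
    def burst_trace(rate=2000.0, t0=2.0, dur_burst=0.1, sd=1.0, level=6.0,
                    total=4.0, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, sd, int(total * rate))
        i0, i1 = int(t0 * rate), int((t0 + dur_burst) * rate)
        y[i0:i1] *= level
        return SignalTrace(y, rate, 0.0, "emg", "µV")

    def test_flat_trace_no_onset(self):
        rng = np.random.default_rng(0)
        tr = SignalTrace(rng.normal(0, 1, 8000), 2000.0)
        assert detect_emg_onset(tr, (0.2, 1.0), (1.0, 3.5)) is None

    def test_sustained_burst_found_near_start(self):
        tr = self.burst_trace(dur_burst=0.15, level=8.0)
        t = detect_emg_onset(tr, (0.5, 1.3), (1.3, 3.0))
        assert t is not None and t == pytest.approx(2.0, abs=0.05)

    def test_short_burst_rejected(self):
        # 30 ms bursts fail the 50 ms persistence requirement
        tr = self.burst_trace(dur_burst=0.03, level=8.0)
        assert detect_emg_onset(tr, (0.5, 1.3), (1.3, 3.0)) is None

    def test_offset_is_peak_with_largest_drop(self):
        rate = 2000.0
        t = np.arange(int(4 * rate)) / rate
        env = np.exp(-0.5 * ((t - 2.0) / 0.15) ** 2)   # burst peaking at 2 s
        rng = np.random.default_rng(1)
        tr = SignalTrace((1 + 6 * env) * rng.normal(0, 1, t.size),
                         rate, 0.0, "emg", "µV")
        off = detect_emg_offset(tr, torque_offset=2.0)
        assert off == pytest.approx(2.0, abs=0.15)

    def test_monotone_decay_has_no_local_max(self):
        rate = 2000.0
        y = np.exp(-np.arange(int(4 * rate)) / rate)
        tr = SignalTrace(y + 1e-6, rate, 0.0, "emg", "µV")
        assert detect_emg_offset(tr, torque_offset=2.0) is None


class TestSegmentation:
    def test_boundaries_match_generator_truth(self, gain_analysis):
        gt = {t["trial_id"]: t
              for t in gain_analysis.session.ground_truth.trial_truth}
        checked = 0
        for tid, seg in gain_analysis.segmentations.items():
            tr = gt[tid]
            if tr["outcome"] != "perfect" or not seg.complete:
                continue
            assert seg.torque_onset == pytest.approx(tr["torque_onset"],
                                                     abs=0.1)
            assert seg.torque_offset == pytest.approx(tr["torque_offset"],
                                                      abs=0.15)
            assert seg.emg_onset == pytest.approx(tr["emg_onset"], abs=0.1)
            assert seg.pm_onset == pytest.approx(tr["pm_onset"], abs=0.1)
            checked += 1
        assert checked >= 10

    def test_epochs_partition_cue_to_end(self, gain_analysis):
        for seg in gain_analysis.segmentations.values():
            if not seg.complete:
                continue
            assert seg.delay[1] == seg.am[0]
            assert seg.am[1] == seg.ah[0]
            ivs = [seg.delay, seg.am, seg.ah]
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                assert a1 <= b0 + 1e-12

    def test_most_perfect_trials_fully_segmented(self, gain_analysis):
        gt = {t["trial_id"]: t["outcome"]
              for t in gain_analysis.session.ground_truth.trial_truth}
        perfect = [tid for tid, o in gt.items() if o == "perfect"]
        complete = [tid for tid in perfect
                    if gain_analysis.segmentations[tid].complete]
        assert len(complete) >= 0.8 * len(perfect)


class TestClassification:
    @staticmethod
    def _trial(direction="flexion"):
        return TrialRecord(0, direction, cue_on=1.0, go=2.0, end_cue=4.0,
                           reward_or_abort=5.5)

    @staticmethod
    def _trace(y, rate=500.0):
        return SignalTrace(y, rate, 0.0, "torque", "N·m")

    def test_zero_torque_is_no_movement(self, rng):
        y = rng.normal(0, 0.005, 3000)
        out = classify_trial(self._trial(), self._trace(y), 1.0)
        assert out == "no_movement"

    def test_opposite_sign_is_wrong_direction(self):
        tr = logistic_ramp(t_on=2.3, amp=-1.0)   # flexion expects +
        out = classify_trial(self._trial("flexion"), tr, 1.0)
        assert out == "wrong_direction"

    def test_torque_dip_is_short_hold(self):
        rate = 500.0
        t = np.arange(int(5.5 * rate)) / rate
        rise = 1.0 / (1 + np.exp(-(t - 2.4) / 0.03))
        fall = 1.0 / (1 + np.exp(-(t - 2.9) / 0.03))
        y = rise - 0.8 * fall          # dips to 0.2x target within 1 s
        out = classify_trial(self._trial("flexion"), self._trace(y), 1.0)
        assert out == "short_hold"

    def test_held_ramp_is_success(self):
        tr = logistic_ramp(t_on=2.3, amp=1.0)
        out = classify_trial(self._trial("flexion"), tr, 1.0)
        assert out == "success"

    def test_threshold_fraction_band_enforced(self):
        tr = logistic_ramp()
        with pytest.raises(ConfigError):
            classify_trial(self._trial(), tr, 1.0, threshold_frac=0.5)
        with pytest.raises(ConfigError):
            classify_trial(self._trial(), tr, -1.0)

    def test_injected_labels_recovered_noise_free(self, clean_session):
        _, outcomes = segment_session(clean_session, target_torque=1.0)
        truth = {t["trial_id"]: t["outcome"]
                 for t in clean_session.ground_truth.trial_truth}
        for tid, want in truth.items():
            got = outcomes[tid]
            if want == "perfect":
                assert got in ("perfect", "success")
            else:
                assert got == want
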