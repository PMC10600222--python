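"""Volley averaging, detection, landmarks, areas and normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from padpipe import (SignalTrace, average_sweeps, conduction_velocity,
                     detect_significant_volley, extract_sweeps,
                     find_landmarks, measure_area, measure_sweeps,
                     normalize_areas)
from padpipe.adv import ADVTemplate
from padpipe.synth import adv_kernel

RATE = 20_000.0


def make_template(post, rate=RATE, baseline_sd=1.0, n_sweeps=100, seed=0):
    """Template whose post-stimulus part is ``post`` riding on noise."""
    rng = np.random.default_rng(seed)
    pre = rng.normal(0, baseline_sd, int(0.3 * rate))
    avg = np.concatenate([pre, post + rng.normal(0, baseline_sd,
                                                 post.size)])
    tr = SignalTrace(avg, rate, -0.3, "adv_avg", "µV")
    b = tr.slice(-0.3, -0.1).samples
    return ADVTemplate(tr, float(b.mean()), float(b.std()),
                       n_sweeps=n_sweeps)


def biphasic_post(rate=RATE, latency_ms=2.0, amp=10.0, width_ms=1.0,
                  post_ms=10.0):
    post = np.zeros(int(post_ms * 1e-3 * rate))
    k = adv_kernel(rate, width_ms, amp)
    i0 = int(latency_ms * 1e-3 * rate)
    post[i0:i0 + k.size] = k
    return post


class TestAveraging:
    def test_identical_sweeps_average_is_sweep(self):
        # spacing > full window so no sweep sees a neighbour's volley
        rate = RATE
        stim_times = 0.5 + np.arange(60) * 0.4
        n = int((stim_times[-1] + 0.1) * rate)
        y = np.zeros(n)
        k = adv_kernel(rate, 1.0, 5.0)
        for t in stim_times:
            i = int(t * rate) + int(0.002 * rate)
            y[i:i + k.size] += k
        tr = SignalTrace(y, rate, 0.0, "DR", "µV")
        tpl = average_sweeps(tr, stim_times)
        one, _ = extract_sweeps(tr, stim_times[:1])
        assert np.allclose(tpl.avg_waveform.samples, one[0], atol=1e-12)

    def test_noise_reduction_follows_sqrt_n(self, rng):
        # CLT check: averaged baseline noise SD ~ sigma / sqrt(n)
        rate, sigma, n_stim = RATE, 2.0, 400
        stim_times = 0.5 + np.arange(n_stim) * 0.1
        n = int((stim_times[-1] + 0.1) * rate)
        tr = SignalTrace(rng.normal(0, sigma, n), rate, 0.0, "DR", "µV")
        tpl = average_sweeps(tr, stim_times)
        expected = sigma / np.sqrt(tpl.n_sweeps)
        assert tpl.baseline_sd == pytest.approx(expected, rel=0.25)

    def test_too_few_stimuli_rejected(self):
        tr = SignalTrace(np.zeros(int(RATE)), RATE)
        with pytest.raises(ValueError, match="at least"):
            average_sweeps(tr, 0.4 + np.arange(10) * 0.01)

    def test_overlapping_post_window_rejected(self):
        tr = SignalTrace(np.zeros(int(60 * RATE)), RATE)
        with pytest.raises(ValueError, match="spacing"):
            average_sweeps(tr, 0.5 + np.arange(60) * 0.005)

    def test_template_waveform_recovered(self, gain_analysis):
        # correlation with the generating kernel > 0.99
        tpl = gain_analysis.template
        rate = tpl.rate
        k = adv_kernel(rate, 1.0, 1.0)
        lat = gain_analysis.session.ground_truth.adv["latency_s"]
        i0 = tpl.avg_waveform.index_at(lat)
        seg = tpl.avg_waveform.samples[i0:i0 + k.size]
        r = np.corrcoef(seg, k)[0, 1]
        assert abs(r) > 0.99


class TestDetection:
    def test_flat_zero_not_significant(self):
        tpl = make_template(np.zeros(int(0.01 * RATE)))
        assert detect_significant_volley(tpl) is False

    def test_large_biphasic_pulse_detected(self):
        tpl = make_template(biphasic_post(amp=10.0, latency_ms=2.0))
        assert detect_significant_volley(tpl) is True

    def test_late_pulse_rejected_by_latency_rule(self):
        tpl = make_template(biphasic_post(amp=10.0, latency_ms=6.0))
        assert detect_significant_volley(tpl) is False

    def test_zero_baseline_sd_degenerate(self):
        avg = np.zeros(int(0.31 * RATE))
        tr = SignalTrace(avg, RATE, -0.3)
        tpl = ADVTemplate(tr, 0.0, 0.0, n_sweeps=50)
        with pytest.raises(ValueError, match="baseline"):
            detect_significant_volley(tpl)


class TestLandmarks:
    def test_symmetric_biphasic_inflection_at_lobe_junction(self):
        tpl = make_template(biphasic_post(amp=20.0, latency_ms=2.0,
                                          width_ms=1.0), baseline_sd=0.01)
        detect_significant_volley(tpl)
        find_landmarks(tpl)
        assert tpl.trough_t < tpl.peak_t
        assert tpl.inflection_t == pytest.approx(2.5, abs=0.1)
        assert tpl.onset_t == pytest.approx(2.0, abs=0.1)
        assert tpl.offset_t == pytest.approx(3.0, abs=0.1)

    def test_monophasic_inflection_equals_offset(self):
        rate = RATE
        post = np.zeros(int(0.01 * rate))
        k = np.sin(np.pi * np.arange(int(0.5e-3 * rate))
                   / int(0.5e-3 * rate)) ** 2 * 15.0
        i0 = int(2e-3 * rate)
        post[i0:i0 + k.size] = k
        tpl = make_template(post, baseline_sd=0.05)
        detect_significant_volley(tpl)
        find_landmarks(tpl)
        assert tpl.inflection_t == tpl.offset_t
        assert len(tpl.lobe_signs) == 1

    def test_landmarks_shift_with_template(self):
        a = make_template(biphasic_post(latency_ms=2.0), baseline_sd=0.01)
        b = make_template(biphasic_post(latency_ms=3.0), baseline_sd=0.01)
        for tpl in (a, b):
            detect_significant_volley(tpl)
            find_landmarks(tpl)
        # crossing times jitter by a few samples where the lobe foot
        # meets the noise floor
        assert b.onset_t - a.onset_t == pytest.approx(1.0, abs=0.2)
        assert b.offset_t - a.offset_t == pytest.approx(1.0, abs=0.2)


class TestArea:
    @staticmethod
    def template_with_landmarks():
        tpl = make_template(biphasic_post(amp=10.0), baseline_sd=0.01)
        detect_significant_volley(tpl)
        return find_landmarks(tpl)

    def test_zero_sweep_zero_area(self):
        tpl = self.template_with_landmarks()
        sweep = np.zeros(len(tpl.avg_waveform))
        assert measure_area(sweep, tpl) == pytest.approx(0.0, abs=1e-12)

    def test_rectangular_lobe_closed_form(self):
        # single positive rectangle of height h over m bins -> h*m*dt_ms
        rate = RATE
        post = np.zeros(int(0.01 * rate))
        m = int(1e-3 * rate)
        i0 = int(2e-3 * rate)
        h = 12.0
        post[i0:i0 + m] = h
        tpl = make_template(post, baseline_sd=0.01)
        detect_significant_volley(tpl)
        find_landmarks(tpl)
        sweep = np.concatenate([np.zeros(int(0.3 * rate)), post])
        got = measure_area(sweep, tpl)
        want = h * m * 1e3 / rate
        assert got == pytest.approx(want, rel=0.05)

    @settings(max_examples=15, deadline=None)
    @given(st.floats(0.5, 4.0))
    def test_area_linear_in_gain(self, gain):
        tpl = self.template_with_landmarks()
        base = np.concatenate([np.zeros(int(0.3 * RATE)),
                               biphasic_post(amp=10.0)])
        a1 = measure_area(base, tpl)
        a2 = measure_area(gain * base, tpl)
        assert a2 == pytest.approx(gain * a1, rel=1e-9)

    def test_area_invariant_to_baseline_offset(self):
        tpl = self.template_with_landmarks()
        base = np.concatenate([np.zeros(int(0.3 * RATE)),
                               biphasic_post(amp=10.0)])
        assert measure_area(base + 5.0, tpl) == \
               pytest.approx(measure_area(base, tpl), rel=1e-9)

    def test_both_lobes_contribute_positively(self):
        tpl = self.template_with_landmarks()
        base = np.concatenate([np.zeros(int(0.3 * RATE)),
                               biphasic_post(amp=10.0)])
        full = measure_area(base, tpl)
        assert full > 0
        # suppressing the positive lobe halves the area (symmetric lobes)
        neg_only = base.copy()
        neg_only[neg_only > 0] = 0.0
        assert measure_area(neg_only, tpl) == pytest.approx(full / 2,
                                                            rel=0.05)


class TestNormalization:
    def test_z_identities(self, rng):
        rest = rng.normal(100.0, 10.0, 200)
        mu, sd = rest.mean(), rest.std()
        z = normalize_areas(np.array([mu, mu + 2 * sd]), rest)
        assert z[0] == pytest.approx(0.0, abs=1e-9)
        assert z[1] == pytest.approx(2.0, abs=1e-9)

    def test_rest_mean_maps_to_zero(self, rng):
        rest = rng.normal(50.0, 5.0, 100)
        z = normalize_areas(rest, rest)
        assert abs(z.mean()) < 1e-12

    def test_requires_enough_rest_measures(self, rng):
        with pytest.raises(ValueError):
            normalize_areas(np.ones(5), rng.normal(0, 1, 10))

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            normalize_areas(np.ones(5), np.ones(30))


class TestConductionVelocity:
    def test_arithmetic(self):
        assert conduction_velocity(2.0, 0.13) == pytest.approx(65.0)

    def test_halved_latency_doubles_velocity(self):
        assert conduction_velocity(1.0, 0.13) == \
               pytest.approx(2 * conduction_velocity(2.0, 0.13))

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            conduction_velocity(0.0, 0.13)
        with pytest.raises(ValueError):
            conduction_velocity(2.0, -1.0)

    def test_session_velocity_matches_generator(self, gain_analysis):
        gt = gain_analysis.session.ground_truth.adv
        got = gain_analysis.template.conduction_velocity
        assert got == pytest.approx(gt["conduction_velocity_m_s"], rel=0.15)


class TestSessionQuantification:
    def test_epoch_gain_visible_in_z_scores(self, gain_analysis):
        # mean z of a gain-g epoch ~ (g-1) * mean_rest / sd_rest
        m = gain_analysis.measures
        rest = m[m.perfect & (m.epoch == "Rest")]["raw_area"]
        pred = (0.8 - 1.0) * rest.mean() / rest.std(ddof=0)
        am_ext = m[m.perfect & (m.epoch == "AM")
                   & (m.direction == "extension")]["z_area"]
        se = am_ext.std(ddof=1) / np.sqrt(len(am_ext))
        assert am_ext.mean() == pytest.approx(pred, abs=3 * se + 0.1)
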