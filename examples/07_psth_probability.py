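"""Response probability of a first-order spinal interneuron.

Each stimulus is followed, with an epoch-dependent probability, by a
spike at the monosynaptic latency.  The peristimulus histogram (0.5 ms
bins) recovers those probabilities from the peak area, and exact
binomial tests compare each epoch against Rest.
"""

from padpipe import (SimConfig, build_psth, epoch_response_tests,
                     generate_session, label_stim_epochs, peak_area)

cfg = SimConfig(n_trials_per_direction=16, neurogram_rate=20_000,
                emg_rate=2_000, torque_rate=500,
                response_prob={"Rest": 0.3, "Delay": 0.3, "AM": 0.7,
                               "AH": 0.3, "PM": 0.3},
                background_rate_hz=5.0)
session = generate_session(cfg, seed=6)
labels = label_stim_epochs(session.stim_times(),
                           session.ground_truth.trial_truth)
valid = labels[labels.epoch.notna()]
results = build_psth(session.spikes, valid.stim_time.to_numpy(),
                     valid.epoch.to_numpy())
for epoch, res in sorted(results.items()):
    p = peak_area(res)
    want = cfg.response_prob[epoch]
    print(f"{epoch:>6}: recovered p={p:.2f} (true {want}) "
          f"from {res.n_stimuli} stimuli")

print("\nbinomial tests vs Rest (Bonferroni size 4):")
print(epoch_response_tests(results).round(4).to_string(index=False))
print("\nThe elevated epoch (AM) is overwhelmingly significant. Note that")
print("the binomial test conditions on the *estimated* Rest probability,")
print("so epochs whose true probability equals Rest can occasionally")
print("reach nominal significance when the Rest estimate itself sits a")
print("couple of standard errors from truth.")
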