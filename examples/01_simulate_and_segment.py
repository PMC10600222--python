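"""Generate a synthetic session and segment its behavioural epochs.

A session bundles wrist torque, two EMG channels, a nerve-cuff neurogram
with 10 Hz intraspinal-microstimulation volleys, and the trial log.  The
epoching stage re-derives movement boundaries from the signals alone, so
we can compare them with the generator's ground truth.
"""

import numpy as np

from padpipe import SimConfig, generate_session, segment_session

cfg = SimConfig(n_trials_per_direction=6, neurogram_rate=20_000,
                emg_rate=2_000, torque_rate=500)
session = generate_session(cfg, seed=0)
segs, outcomes = segment_session(session, target_torque=cfg.target_torque)

truth = {t["trial_id"]: t for t in session.ground_truth.trial_truth}
errs = []
for tid, seg in segs.items():
    t = truth[tid]
    if t["outcome"] == "perfect" and seg.torque_onset is not None:
        errs.append(abs(seg.torque_onset - t["torque_onset"]))
    print(f"trial {tid:2d} {t['direction']:>9}  injected={t['outcome']:<12}"
          f" classified={outcomes[tid]}")

print(f"\nmedian torque-onset error: {1e3 * np.median(errs):.1f} ms")
print("Onset errors of a few tens of ms reflect the 5 Hz zero-phase")
print("smoothing; classification should reproduce every injected label.")
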