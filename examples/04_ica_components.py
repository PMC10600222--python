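"""Decompose a volley population's epoch profiles with bootstrap ICA.

A population of 77 volleys carries two latent modulation patterns: a
transient centred on active movement (both directions) and a sustained
facilitation confined to flexion rows.  ICA on the 154 x 4 epoch-mean
matrix should recover both, with bootstrap CIs bracketing the truth.
"""

import numpy as np

from padpipe import (PopulationComponent, align_components, bootstrap_ci,
                     build_matrix, generate_profile_population,
                     reconstruct_timecourse)
from padpipe.synth import AM_TRANSIENT_PATTERN, FLEXION_SUSTAINED_PATTERN

comps = [PopulationComponent(AM_TRANSIENT_PATTERN),
         PopulationComponent(FLEXION_SUSTAINED_PATTERN,
                             flexion_scale=1.5, extension_scale=0.0)]
profiles, truth = generate_profile_population(77, comps, noise_sd=0.2,
                                              seed=0)
X, _ = build_matrix(profiles)
print(f"data matrix: {X.shape[0]} rows x {X.shape[1]} epochs "
      "(flexion block stacked on extension)")

res = bootstrap_ci(X, n_comp=2, n_boot=300, seed=0)
_, _, matched = align_components(truth["patterns"], res.components,
                                 res.weights)
epochs = ["Delay", "AM", "AH", "PM"]
for k in range(2):
    row = "  ".join(f"{e}:{v:+.2f}" for e, v in zip(epochs,
                                                    res.components[k]))
    print(f"IC{k + 1}: {row}")
print(f"|correlation| with embedded patterns after alignment: "
      f"{np.round(matched, 3)}")

t, y = reconstruct_timecourse(res.components[0],
                              res.median_weights("flexion")[0])
print(f"\nreconstructed IC1 time course: {y.size} points over {t[-1]:.2f} s"
      f" (peak {y.max():+.2f} z)")
print("Matched correlations near 1 mean the latent patterns were")
print("recovered despite ICA's sign/order indeterminacy.")
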