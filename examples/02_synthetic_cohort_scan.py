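"""End-to-end per-scale classification on a synthetic two-group cohort.

Generates a small cohort in which the MDD group carries extra signal
irregularity pinned to temporal scale 3, extracts RCMSE+RCMPE features
per 10-s epoch, runs the four classifiers under 10-fold cross-validation
at every scale, and locates the optimal scale with the forward-difference
zero-crossing rule.  Expect the classifier-averaged accuracy to peak at
scale 3 — the scale the generator targeted.

Runtime: a couple of minutes on one CPU.
"""

import numpy as np

from mseeg import (CohortSpec, EntropyConfig, analyze_scale_curve,
                   generate_cohort, scale_scan)
from mseeg.preprocessing import segment_epochs

spec = CohortSpec(n_hc=8, n_mdd=8, n_channels=4, duration=60.0,
                  effect_scale=3, effect_size=0.4, seed=42)
epochs = []
for rec in generate_cohort(spec):
    epochs.extend(segment_epochs(rec, 10.0))
print(f"{len(epochs)} epochs from {spec.n_hc + spec.n_mdd} subjects")

table = scale_scan(epochs, EntropyConfig(), seed=7)
print("\naccuracy grid (classifier x scale):")
print(table.grid("accuracy").round(3).to_string())

avg = table.classifier_average()["accuracy"]
res = analyze_scale_curve(avg.to_numpy())
print("\nclassifier-averaged accuracy per scale:")
print(avg.round(3).to_string())
print("\nforward difference f'(tau):", np.round(res.f_prime, 3))
print("detected extrema:", res.extrema)
print("\nA (tau, 'max') entry at tau=3 means the positive-to-negative "
      "zero crossing of f' recovered the scale where the group contrast "
      "was injected.")
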