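"""Per-electrode group t-test map across temporal scales.

Builds a synthetic cohort with a scale-3 complexity contrast, then runs an
independent-samples t-test per (electrode, scale, entropy measure) on the
per-epoch feature values, printing the p-value table with non-significant
cells blanked — the univariate view of where (in space and scale) the
group difference lives.
"""

from mseeg import CohortSpec, EntropyConfig, generate_cohort, ttest_table
from mseeg.features import extract_feature_curves
from mseeg.preprocessing import segment_epochs

spec = CohortSpec(n_hc=6, n_mdd=6, n_channels=5, duration=40.0,
                  effect_scale=3, effect_size=0.5, seed=9)
epochs = []
for rec in generate_cohort(spec):
    epochs.extend(segment_epochs(rec, 10.0))

fms = extract_feature_curves(epochs, EntropyConfig(tau_max=6))
tt = ttest_table(fms, alpha=0.05)

for measure in ("RCMSE", "RCMPE"):
    print(f"\n{measure} p-values (cells > 0.05 blanked):")
    print(tt.masked(measure).map(
        lambda p: f"{p:.1e}" if p == p else "").to_string())

print("\nEvery channel carries the injected contrast, so significant "
      "cells should concentrate around scale 3 and above for RCMPE, "
      "with scale 1 also separable (the injected narrowband component "
      "lowers fine-scale permutation entropy).")
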