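"""The analytic cost model of multiscale feature extraction, vs reality.

Prints the predicted decomposition E(tau) = T1 + T2 + T3 (sample-entropy
kernels, permutation-entropy kernels, coarse-graining) for nominal
constants, then measures actual wall time of RCMSE+RCMPE extraction on a
10-s 19-channel epoch for scales 1..10, fits the model to the
measurements, and reports the linearity of time vs scale.
"""

import numpy as np

from mseeg import EntropyConfig, predicted_costs, profile_scaling

L = 2560.0
print("predicted costs, nominal constants (arbitrary units):")
print(f"{'tau':>4} {'T1':>10} {'T2':>10} {'T3':>10} {'E':>10}")
for tau in range(1, 11):
    p = predicted_costs(tau, L, a=1e-9, b=1e-6, c1=1e-6, c2=1.2e-6)
    print(f"{tau:>4} {p.t1:>10.4f} {p.t2:>10.4f} {p.t3:>10.4f} "
          f"{p.total:>10.4f}")

print("\nmeasuring actual extraction times (19-channel 10-s epoch)...")
epoch = np.random.default_rng(0).standard_normal((19, int(L)))
table, model, r = profile_scaling(epoch, EntropyConfig(), repeats=5)
print(table.round(4).to_string())
print(f"\nPearson r(time, tau) = {r:.3f};  fit R^2 = "
      f"{model.r_squared:.3f}")
print("A correlation near 1 says the extra cost of coarser scales is "
      "predictable and roughly linear — multiscale analysis buys its "
      "extra discriminative power at a known, bounded price.")
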