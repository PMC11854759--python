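"""Coarse-graining and the two refined composite multiscale entropies.

Computes RCMSE and RCMPE of three reference signals — white noise, pink
(1/f) noise and a pure sinusoid — across temporal scales 1..10 and prints
the curves.  White noise is maximally irregular at the original sampling
but loses complexity under coarse-graining; pink noise keeps its entropy
roughly flat across scales (the classic signature of long-range
correlation); the sinusoid is low-entropy everywhere.
"""

import numpy as np

from mseeg import EntropyConfig, entropy_curve, generate_reference_signal

cfg = EntropyConfig()          # m=2, r=0.15*sigma, m_pe=4, scales 1..10

print(f"{'tau':>4} | {'RCMSE w/p/s':>24} | {'RCMPE w/p/s':>24}")
curves = {kind: entropy_curve(generate_reference_signal(kind, 20_000, seed=1),
                              cfg)
          for kind in ("white", "pink", "periodic")}
for tau in range(1, cfg.tau_max + 1):
    se = " ".join(f"{curves[k][0][tau - 1]:7.3f}"
                  for k in ("white", "pink", "periodic"))
    pe = " ".join(f"{curves[k][1][tau - 1]:7.3f}"
                  for k in ("white", "pink", "periodic"))
    print(f"{tau:>4} | {se} | {pe}")

print()
print("RCMPE of white noise at scale 1 approaches ln(4!) =",
      f"{np.log(24):.3f} nats (all 24 ordinal patterns equally likely);")
print("the sinusoid stays far below it, and white-noise RCMSE decreases")
print("with scale as block-averaging smooths the series.")
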