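"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions, deliberately avoiding the
code paths of the package (no KDTree counting, no vectorised pattern
encoding, no scipy.stats t-test), so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import betainc


def coarse_grain_loop(x, tau):
    x = np.asarray(x, dtype=float)
    n = len(x) // tau
    return np.array([x[j * tau:(j + 1) * tau].sum() / tau
                     for j in range(n)])


def sampen_counts_bruteforce(y, m, r):
    """Ordered-pair template match counts via full distance matrices."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_templ = n - m

    def count(length):
        tem = np.array([y[i:i + length] for i in range(n_templ)])
        # Chebyshev distances via explicit per-dimension maxima
        d = np.zeros((n_templ, n_templ))
        for k in range(length):
            d = np.maximum(d, np.abs(tem[:, k][:, None] - tem[:, k][None, :]))
        match = d <= r
        np.fill_diagonal(match, False)
        return int(match.sum())

    return count(m), count(m + 1)


def rcmse_bruteforce(x, tau, m=2, r_coef=0.15, variant="cumulative"):
    x = np.asarray(x, dtype=float)
    r = r_coef * x.std()
    if variant == "cumulative":
        series = [coarse_grain_loop(x, k) for k in range(1, tau + 1)]
    else:
        series = [coarse_grain_loop(x[s:], tau) for s in range(tau)]
    tot_m = tot_m1 = 0
    for y in series:
        a, b = sampen_counts_bruteforce(y, m, r) if len(y) > m + 1 \
            else (0, 0)
        tot_m += a
        tot_m1 += b
    if tot_m == 0 and tot_m1 == 0:
        return None                      # undefined
    if tot_m1 == 0:
        return math.inf
    return -math.log(tot_m1 / tot_m)


def pattern_freq_bruteforce(y, m, delay=1):
    """Ordinal pattern frequencies by explicit window enumeration."""
    y = np.asarray(y, dtype=float)
    counts: dict[tuple, int] = {}
    n_win = len(y) - (m - 1) * delay
    for i in range(n_win):
        w = y[i:i + (m - 1) * delay + 1:delay]
        # stable rank: order of indices sorted by (value, index)
        pattern = tuple(sorted(range(m), key=lambda j: (w[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    all_patterns = list(itertools.permutations(range(m)))
    freq = np.array([counts.get(p, 0) for p in all_patterns], dtype=float)
    return freq / n_win


def rcmpe_bruteforce(x, tau, m=4, delay=1, variant="cumulative"):
    x = np.asarray(x, dtype=float)
    if variant == "cumulative":
        series = [coarse_grain_loop(x, k) for k in range(1, tau + 1)]
    else:
        series = [coarse_grain_loop(x[s:], tau) for s in range(tau)]
    freqs = [pattern_freq_bruteforce(y, m, delay) for y in series
             if len(y) >= (m - 1) * delay + 1]
    p = np.mean(freqs, axis=0)
    return float(-sum(pi * math.log(pi) for pi in p if pi > 0))


def ttest_pvalue_oracle(a, b):
    """Equal-variance two-sample t-test p-value via the incomplete beta."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    # two-sided p from the regularised incomplete beta
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def local_maxima_bruteforce(f):
    """Interior points strictly greater than both neighbours (1-based)."""
    f = np.asarray(f, dtype=float)
    return [i + 1 for i in range(1, len(f) - 1)
            if f[i] > f[i - 1] and f[i] > f[i + 1]]


def cost_sums_loop(tau):
    s2 = sum(1.0 / k**2 for k in range(1, tau + 1))
    s1 = sum(1.0 / k for k in range(1, tau + 1))
    return s2, s1


def metrics_oracle(tp, fp, fn, tn):
    total = tp + fp + fn + tn
    out = {"accuracy": (tp + tn) / total}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else math.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else math.nan
    out["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan
    return out
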