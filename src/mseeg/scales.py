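"""Temporal-scale analysis: group t-tests, forward differences, extrema.

Two complementary views of "which scale matters":

* per-electrode independent-samples t-tests of the entropy values between
  groups, one test per (electrode, scale, measure) — a univariate map of
  where the group contrast lives;
* the discrete metric-vs-scale function f(tau) from the classification
  grid, analysed through its forward difference f'(tau) = f(tau+1) -
  f(tau): a zero crossing of f' from positive to negative marks a local
  maximum of f.

The t-tests are Student's (equal-variance) two-sided tests on per-epoch
entropy values pooled across subjects by default; pooling epochs treats
them as independent, which understates p-values on real data where epochs
of one subject are correlated.  A per-subject-mean mode avoids that at the
cost of power.  No multiple-comparison correction is applied; the table
reports raw p-values with an alpha mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

__all__ = [
    "GroupTestTable",
    "ScaleScanResult",
    "group_ttest",
    "ttest_table",
    "forward_difference",
    "detect_local_maxima",
    "detect_local_minima",
    "analyze_scale_curve",
]


def group_ttest(values_a, values_b) -> float:
    """Two-sided independent two-sample Student t-test p-value.

    Equal variances are assumed (classic Student's t, not Welch).  If both
    groups have zero variance and equal means the statistic is 0/0; p = 1
    by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass
class GroupTestTable:
    """p-values per (electrode, scale) for each entropy measure.

    ``pvalues`` maps measure name ("RCMSE" / "RCMPE") to an electrodes x
    scales DataFrame.  ``masked()`` blanks the cells above ``alpha`` (NaN),
    mirroring the convention of reporting only significant entries.
    """

    pvalues: dict[str, pd.DataFrame]
    alpha: float = 0.05

    def significant(self, measure: str) -> pd.DataFrame:
        return self.pvalues[measure] <= self.alpha

    def masked(self, measure: str) -> pd.DataFrame:
        p = self.pvalues[measure]
        return p.where(p <= self.alpha)


def _electrodes_from_columns(columns: list[str], suffix: str) -> list[str]:
    return [c[: -len(suffix) - 1] for c in columns if c.endswith(suffix)]


def ttest_table(feature_matrices: dict[int, FeatureMatrix],
                alpha: float = 0.05,
                unit: str = "epoch") -> GroupTestTable:
    """Group t-tests per (electrode, scale, measure) from feature matrices.

    ``unit='epoch'`` (default) pools per-epoch entropy values across
    subjects; ``unit='subject'`` tests per-subject means.  Both groups must
    be present in every matrix.
    """
    if unit not in ("epoch", "subject"):
        raise ValueError(f"unit must be 'epoch' or 'subject', got {unit!r}")
    taus = sorted(feature_matrices)
    first = feature_matrices[taus[0]]
    electrodes = _electrodes_from_columns(first.column_names, "RCMSE")
    out = {meas: pd.DataFrame(np.nan, index=electrodes,
                              columns=pd.Index(taus, name="tau"))
           for meas in ("RCMSE", "RCMPE")}
    for tau in taus:
        fm = feature_matrices[tau]
        labels = np.asarray(fm.y)
        if len(set(labels)) < 2:
            raise ValueError(f"matrix at tau={tau} has a single group")
        for meas in ("RCMSE", "RCMPE"):
            for el in electrodes:
                col = fm.column_names.index(f"{el}_{meas}")
                vals = fm.X[:, col]
                a, b = vals[labels == "HC"], vals[labels == "MDD"]
                if unit == "subject":
                    sid = np.asarray(fm.subject_ids)
                    a = np.array([vals[(sid == s) & (labels == "HC")].mean()
                                  for s in pd.unique(sid[labels == "HC"])])
                    b = np.array([vals[(sid == s) & (labels == "MDD")].mean()
                                  for s in pd.unique(sid[labels == "MDD"])])
                out[meas].loc[el, tau] = group_ttest(a, b)
    return GroupTestTable(out, alpha)


def forward_difference(f) -> np.ndarray:
    """f'(tau) = f(tau+1) - f(tau); length len(f) - 1."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    return np.diff(f)


def _zero_crossings(f: np.ndarray, sign: int) -> list[int]:
    d = forward_difference(f)
    out = []
    for tau in range(2, len(f)):          # interior points only, 1-based
        if sign * d[tau - 2] > 0 and sign * d[tau - 1] < 0:
            out.append(tau)
    return out


def detect_local_maxima(f) -> list[int]:
    """1-based scales tau* where f'(tau*-1) > 0 and f'(tau*) < 0.

    Endpoints are never reported; an exact zero in f' (plateau) produces
    no sign change and hence no extremum.
    """
    f = np.asarray(f, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 points to detect interior extrema")
    return _zero_crossings(f, +1)


def detect_local_minima(f) -> list[int]:
    """1-based scales where f' crosses zero from negative to positive."""
    f = np.asarray(f, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 points to detect interior extrema")
    return _zero_crossings(f, -1)


@dataclass
class ScaleScanResult:
    """A metric-vs-scale curve with its forward difference and extrema."""

    f: np.ndarray
    f_prime: np.ndarray
    extrema: list[tuple[int, str]]        # (tau*, "max" | "min")


def analyze_scale_curve(f) -> ScaleScanResult:
    """Forward difference and zero-crossing extrema of a metric curve f(tau)."""
    f = np.asarray(f, dtype=float)
    extrema = [(t, "max") for t in detect_local_maxima(f)]
    extrema += [(t, "min") for t in detect_local_minima(f)]
    extrema.sort()
    return ScaleScanResult(f, forward_difference(f), extrema)
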