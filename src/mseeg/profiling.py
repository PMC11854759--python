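"""Analytic cost model of multiscale entropy extraction, plus a timing harness.

For an original series of length L, computing the refined composite
entropies at scale tau touches the coarse-grained series at scales
k = 1..tau (lengths L/k).  With sample entropy quadratic and permutation
entropy linear in series length, and coarse-graining costing k-1 additions
and one multiplication per output sample, the predicted wall time
decomposes as::

    T1(tau) = a L^2 * sum_{k=1}^{tau} 1/k^2     (sample-entropy kernels)
    T2(tau) = b L   * sum_{k=1}^{tau} 1/k       (permutation-entropy kernels)
    T3(tau) = c1 L tau + (c2 - c1) L * sum 1/k  (coarse-graining)
    E(tau)  = T1 + T2 + T3

with machine-dependent constants a, b (per-operation entropy costs) and
c1, c2 (one addition / one multiplication).  The partial sums converge, so
for growing tau the linear coarse-graining term dominates and E(tau) is
asymptotically linear in tau — the hardware-agnostic shape property the
timing harness checks.  When c1 = c2, T3 = c1 L tau exactly.

Only the *shape* of measured timings (correlation, R^2 of the fit) is ever
asserted; absolute seconds are hardware-bound.  Fitting note: b and c2
enter the model only through the combined coefficient of L * sum 1/k, so
they are not separately identifiable from timings; the fit reports the
convention c2 = c1, folding the rest into b.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from .entropy import EntropyConfig, rcmpe, rcmse

__all__ = [
    "CostModel",
    "PredictedCosts",
    "predicted_costs",
    "fit_cost_constants",
    "measure_extraction_times",
    "profile_scaling",
]


class PredictedCosts(NamedTuple):
    t1: float
    t2: float
    t3: float
    total: float


def _partial_sums(tau: int) -> tuple[float, float]:
    k = np.arange(1, tau + 1, dtype=float)
    return float((1.0 / k**2).sum()), float((1.0 / k).sum())


def predicted_costs(tau: int, L: float, a: float, b: float,
                    c1: float, c2: float) -> PredictedCosts:
    """Predicted (T1, T2, T3, E) at scale ``tau`` for the given constants."""
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    if min(a, b, c1, c2) < 0:
        raise ValueError("cost constants must be nonnegative")
    s2, s1 = _partial_sums(tau)
    t1 = a * L**2 * s2
    t2 = b * L * s1
    t3 = c1 * L * tau + (c2 - c1) * L * s1
    return PredictedCosts(t1, t2, t3, t1 + t2 + t3)


@dataclass(frozen=True)
class CostModel:
    """Fitted or assumed cost constants for a series of length L."""

    L: float
    a: float
    b: float
    c1: float
    c2: float
    intercept: float = 0.0
    r_squared: float = float("nan")

    def predict(self, taus: Sequence[int]) -> pd.DataFrame:
        rows = []
        for tau in taus:
            p = predicted_costs(tau, self.L, self.a, self.b, self.c1,
                                self.c2)
            rows.append({"tau": tau, "T1": p.t1, "T2": p.t2, "T3": p.t3,
                         "E": p.total + self.intercept})
        return pd.DataFrame(rows).set_index("tau")


def fit_cost_constants(taus: Sequence[int], seconds: Sequence[float],
                       L: float) -> CostModel:
    """Nonnegative least squares of measured times onto the cost basis.

    The design is {L^2 * sum 1/k^2, L * sum 1/k, L * tau, 1}; coefficients
    are constrained nonnegative.  Returns a :class:`CostModel` under the
    c2 = c1 convention (see module docstring) with the R^2 of the fitted
    E(tau) against the measurements.
    """
    taus = np.asarray(list(taus), dtype=int)
    y = np.asarray(list(seconds), dtype=float)
    if len(taus) != len(y):
        raise ValueError("taus and seconds must have equal length")
    if len(taus) < 4:
        raise ValueError("need >= 4 measurement points")
    if len(np.unique(taus)) != len(taus):
        raise ValueError("tau values must be distinct")
    sums = np.array([_partial_sums(int(t)) for t in taus])
    design = np.column_stack([
        L**2 * sums[:, 0],
        L * sums[:, 1],
        L * taus.astype(float),
        np.ones_like(y),
    ])
    coef, _ = nnls(design, y)
    fitted = design @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    a, b, c1, intercept = (float(v) for v in coef)
    return CostModel(L=L, a=a, b=b, c1=c1, c2=c1, intercept=intercept,
                     r_squared=r2)


def measure_extraction_times(x, cfg: EntropyConfig = EntropyConfig(),
                             taus: Sequence[int] | None = None,
                             repeats: int = 5) -> pd.Series:
    """Wall time of RCMSE+RCMPE feature extraction of ``x`` at each scale.

    ``x`` may be a single series or a channels x samples matrix (a whole
    epoch); the timed unit is the extraction of both entropies for every
    channel at that scale, which averages data-dependent cost variation
    across channels.

    Timing is organised to be robust against clock drift (CPU frequency
    scaling, thermal throttling, background load), which on shared
    machines can dwarf the per-scale differences: one untimed warm-up
    sweep over all scales, then ``repeats`` timed sweeps, each visiting
    the scales in a fresh random order so residual within-sweep drift is
    uncorrelated with tau.  Each sweep's time vector is normalised by its
    own total — a sweep-level multiplicative drift (the clock running
    uniformly slower during one sweep) cancels exactly — and the
    normalised shapes are averaged, then rescaled by the median sweep
    total so the result is still in seconds.  Only the relative shape
    across scales is meaningful.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if taus is None:
        taus = range(1, cfg.tau_max + 1)
    taus = [int(t) for t in taus]
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    order_rng = np.random.default_rng(0)   # fixed: only shuffles visit order
    sweeps: list[dict[int, float]] = []
    for rep in range(repeats + 1):
        visit = list(taus)
        order_rng.shuffle(visit)
        sweep: dict[int, float] = {}
        for tau in visit:
            t0 = time.perf_counter()
            for channel in x:
                rcmse(channel, tau, cfg)
                rcmpe(channel, tau, cfg)
            sweep[tau] = time.perf_counter() - t0
        if rep > 0:                        # first sweep is warm-up
            sweeps.append(sweep)
    mat = np.array([[s[tau] for tau in taus] for s in sweeps])
    totals = mat.sum(axis=1)
    shape = np.median(mat / totals[:, None], axis=0)
    out = shape / shape.sum() * float(np.median(totals))
    return pd.Series(out, index=pd.Index(taus, name="tau"),
                     name="seconds")


def profile_scaling(x, cfg: EntropyConfig = EntropyConfig(),
                    taus: Sequence[int] | None = None,
                    repeats: int = 5) -> tuple[pd.DataFrame, CostModel, float]:
    """Measure extraction times, fit the cost model, report linearity.

    Returns ``(table, model, pearson_r)`` where ``table`` holds measured
    and fitted seconds per scale and ``pearson_r`` is the correlation of
    measured time with tau (the linearity check).
    """
    x = np.asarray(x, dtype=float)
    measured = measure_extraction_times(x, cfg, taus, repeats)
    model = fit_cost_constants(measured.index, measured.values,
                               L=x.shape[-1])
    fitted = model.predict(measured.index)["E"]
    r = float(pearsonr(measured.index.to_numpy(float),
                       measured.values)[0])
    table = pd.DataFrame({"measured": measured, "fitted": fitted})
    return table, model, r
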