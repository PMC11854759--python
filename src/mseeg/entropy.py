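"""Coarse-graining, sample/permutation entropy, and refined composite multiscale variants.

The two headline quantities are RCMSE (refined composite multiscale sample
entropy) and RCMPE (refined composite multiscale permutation entropy).  Both
coarse-grain a series at several temporal scales, pool the *intermediate*
statistics (template-match counts, ordinal-pattern frequencies) across the
coarse-grained series, and only then take the entropy.  Pooling before the
logarithm keeps the estimate defined on short series, where a single scale
may yield zero template matches.

Two pooling conventions are implemented:

``cumulative``
    pool over the coarse-grained series at *every* scale k = 1..tau
    (the default);
``offset_composite``
    pool over the tau offset-shifted coarse-grainings at scale tau
    (the original refined-composite formulation of Wu et al. for MSE and
    Humeau-Heurtier et al. for MPE).

All entropies are in nats.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

__all__ = [
    "EntropyConfig",
    "UndefinedEntropyError",
    "coarse_grain",
    "sample_entropy_counts",
    "sample_entropy",
    "permutation_frequencies",
    "permutation_entropy",
    "ordinal_patterns",
    "rcmse",
    "rcmpe",
    "entropy_curve",
]

VARIANTS = ("cumulative", "offset_composite")


class UndefinedEntropyError(ValueError):
    """Raised when template-match counts are zero at every pooled scale."""


@dataclass(frozen=True)
class EntropyConfig:
    """Hyper-parameters of the multiscale entropy features.

    Parameters
    ----------
    m_se : int
        Embedding dimension of sample entropy (template length).
    r_coef : float
        Tolerance coefficient; the match radius is ``r_coef * sigma`` where
        sigma is the standard deviation of the scale-1 (original) series,
        held fixed across coarse-graining scales.
    m_pe : int
        Ordinal-pattern length for permutation entropy; must lie in [3, 7]
        for the pattern statistics to be estimable from typical epochs.
    delay : int
        Lag between samples of an ordinal pattern (Bandt-Pompe delay).
    tau_max : int
        Largest temporal scale evaluated.
    variant : str
        ``cumulative`` or ``offset_composite`` (see module docstring).
    """

    m_se: int = 2
    r_coef: float = 0.15
    m_pe: int = 4
    delay: int = 1
    tau_max: int = 10
    variant: str = "cumulative"

    def __post_init__(self) -> None:
        if self.m_se < 1:
            raise ValueError(f"m_se must be >= 1, got {self.m_se}")
        if not 3 <= self.m_pe <= 7:
            raise ValueError(f"m_pe must lie in [3, 7], got {self.m_pe}")
        if self.r_coef <= 0:
            raise ValueError(f"r_coef must be > 0, got {self.r_coef}")
        if self.delay < 1:
            raise ValueError(f"delay must be >= 1, got {self.delay}")
        if self.tau_max < 1:
            raise ValueError(f"tau_max must be >= 1, got {self.tau_max}")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    return x


def coarse_grain(x, tau: int) -> np.ndarray:
    """Block-average ``x`` at temporal scale ``tau``.

    Each block of ``tau`` consecutive samples is replaced by its mean;
    the trailing remainder of fewer than ``tau`` samples is dropped, so the
    result has ``floor(len(x) / tau)`` samples.  ``tau == 1`` returns the
    series unchanged.
    """
    x = _as_series(x)
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    if tau > len(x):
        raise ValueError(f"tau={tau} exceeds series length {len(x)}")
    if tau == 1:
        return x.copy()
    n = len(x) // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def _offset_coarse_grain(x: np.ndarray, tau: int, offset: int) -> np.ndarray:
    """Coarse-grain at scale tau starting from sample ``offset`` (0-based)."""
    return coarse_grain(x[offset:], tau)


def _templates(y: np.ndarray, m: int) -> np.ndarray:
    return sliding_window_view(y, m)


def sample_entropy_counts(y, m: int, r: float) -> tuple[int, int]:
    """Raw template-match counts of sample entropy.

    Returns ``(n_m, n_m1)``: the number of *ordered* pairs (i, j), i != j,
    of m-length (resp. (m+1)-length) templates whose Chebyshev distance is
    <= ``r``.  Both counts use the same N - m template start positions so
    the two lengths are comparable; self-matches are excluded.  The counts
    are unnormalised — the normalisation cancels in the refined-composite
    ratio.
    """
    y = _as_series(y)
    n = len(y)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    n_templ = n - m
    xm = _templates(y, m)[:n_templ]
    xm1 = _templates(y, m + 1)
    n_m = _count_pairs(xm, r)
    n_m1 = _count_pairs(xm1, r)
    return n_m, n_m1


def _count_pairs(templates: np.ndarray, r: float) -> int:
    """Ordered template pairs (i != j) within Chebyshev distance r."""
    tree = cKDTree(templates)
    total = tree.count_neighbors(tree, r, p=np.inf)
    return int(total) - len(templates)


def sample_entropy(y, m: int = 2, r: float | None = None,
                   r_coef: float = 0.15) -> float:
    """Classic sample entropy ``-ln(n_{m+1} / n_m)`` of a single series.

    If ``r`` is None it defaults to ``r_coef * std(y)``.
    """
    y = _as_series(y)
    if r is None:
        r = r_coef * y.std()
    n_m, n_m1 = sample_entropy_counts(y, m, r)
    if n_m == 0:
        if n_m1 == 0:
            raise UndefinedEntropyError(
                "no template matches at either length; sample entropy undefined"
            )
        raise UndefinedEntropyError("no m-length template matches")
    if n_m1 == 0:
        return math.inf
    return -math.log(n_m1 / n_m)


@lru_cache(maxsize=None)
def ordinal_patterns(m: int) -> tuple[tuple[int, ...], ...]:
    """All m! ordinal patterns of length ``m`` in lexicographic order."""
    return tuple(itertools.permutations(range(m)))


@lru_cache(maxsize=None)
def _pattern_rank_lookup(m: int) -> np.ndarray:
    """Map the base-m code of a permutation to its lexicographic rank."""
    lookup = np.full(m**m, -1, dtype=np.int64)
    base = m ** np.arange(m, dtype=np.int64)
    for rank, perm in enumerate(ordinal_patterns(m)):
        lookup[int(np.dot(np.asarray(perm, dtype=np.int64), base))] = rank
    return lookup


def permutation_frequencies(y, m: int, delay: int = 1) -> np.ndarray:
    """Relative frequencies of ordinal patterns in ``y``.

    Each window ``(y[i], y[i+delay], ..., y[i+(m-1)*delay])`` is mapped to
    the permutation that sorts it; ties are broken by index order (stable
    sort), so a constant window yields the ascending pattern.  Returns a
    vector of length m! aligned with :func:`ordinal_patterns`.
    """
    y = _as_series(y)
    if not 2 <= m <= 7:
        raise ValueError(f"m must lie in [2, 7], got {m}")
    if delay < 1:
        raise ValueError(f"delay must be >= 1, got {delay}")
    span = (m - 1) * delay + 1
    if len(y) < span:
        raise ValueError(
            f"series of length {len(y)} too short for m={m}, delay={delay}"
        )
    windows = sliding_window_view(y, span)[:, ::delay]
    perms = np.argsort(windows, axis=1, kind="stable")
    base = m ** np.arange(m, dtype=np.int64)
    codes = perms @ base
    ranks = _pattern_rank_lookup(m)[codes]
    freq = np.bincount(ranks, minlength=math.factorial(m)).astype(float)
    return freq / freq.sum()


def _shannon(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*ln(0) = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def permutation_entropy(y, m: int = 4, delay: int = 1) -> float:
    """Classic permutation entropy (nats); lies in [0, ln(m!)]."""
    return _shannon(permutation_frequencies(y, m, delay))


def _pooled_series(x: np.ndarray, tau: int, variant: str) -> list[np.ndarray]:
    """The coarse-grained series whose statistics are pooled at scale tau."""
    if variant == "cumulative":
        return [coarse_grain(x, k) for k in range(1, tau + 1)]
    return [_offset_coarse_grain(x, tau, s) for s in range(tau)]


def rcmse(x, tau: int, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Refined composite multiscale sample entropy at scale ``tau``.

    Template-match counts are computed on each pooled coarse-grained series
    (scales 1..tau for ``cumulative``; the tau offsets at scale tau for
    ``offset_composite``), summed, and the entropy is
    ``-ln(sum n_{m+1} / sum n_m)``.  The match radius is
    ``r_coef * std(x)``, fixed across pooled scales.  At ``tau == 1`` both
    variants reduce to classic sample entropy.

    Raises
    ------
    UndefinedEntropyError
        If the counts at both template lengths are zero on every pooled
        series — the only case in which the composite ratio is undefined.
    """
    x = _as_series(x)
    _check_scale(x, tau, cfg, kind="se")
    r = cfg.r_coef * x.std()
    # an offset-shifted coarse series may be one sample shorter than
    # floor(N/tau); one too short to form any template pair contributes
    # zero counts instead of failing the whole composite
    counts = [sample_entropy_counts(y, cfg.m_se, r)
              if len(y) > cfg.m_se + 1 else (0, 0)
              for y in _pooled_series(x, tau, cfg.variant)]
    return _rcmse_from_counts(counts)


def _rcmse_from_counts(counts: list[tuple[int, int]]) -> float:
    tot_m = sum(c[0] for c in counts)
    tot_m1 = sum(c[1] for c in counts)
    if tot_m == 0 and tot_m1 == 0:
        raise UndefinedEntropyError(
            "zero template matches at every pooled scale"
        )
    if tot_m1 == 0:
        return math.inf
    return -math.log(tot_m1 / tot_m)


def rcmpe(x, tau: int, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Refined composite multiscale permutation entropy at scale ``tau``.

    Ordinal-pattern frequencies are computed on each pooled coarse-grained
    series, averaged pattern-wise, and the Shannon entropy of the averaged
    distribution is returned.  Lies in [0, ln(m_pe!)]; at ``tau == 1`` both
    variants reduce to classic permutation entropy.
    """
    x = _as_series(x)
    _check_scale(x, tau, cfg, kind="pe")
    span = (cfg.m_pe - 1) * cfg.delay + 1
    freqs = [permutation_frequencies(y, cfg.m_pe, cfg.delay)
             for y in _pooled_series(x, tau, cfg.variant) if len(y) >= span]
    return _shannon(np.mean(freqs, axis=0))


def _check_scale(x: np.ndarray, tau: int, cfg: EntropyConfig, kind: str) -> None:
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    n_coarse = len(x) // tau
    if kind == "se":
        if n_coarse <= cfg.m_se + 1:
            raise ValueError(
                f"series of length {len(x)} too short for rcmse at tau={tau}"
            )
    else:
        if n_coarse < (cfg.m_pe - 1) * cfg.delay + 1:
            raise ValueError(
                f"series of length {len(x)} too short for rcmpe at tau={tau}"
            )


def entropy_curve(x, cfg: EntropyConfig = EntropyConfig()
                  ) -> tuple[np.ndarray, np.ndarray]:
    """RCMSE and RCMPE of ``x`` at every scale tau = 1..cfg.tau_max.

    Returns ``(rcmse_values, rcmpe_values)``, each of length ``tau_max``,
    with element tau-1 equal to the corresponding individual call.  Scales
    that are undefined for this series (too short, or zero matches
    everywhere) are recorded as NaN rather than raised.

    For the ``cumulative`` variant the per-scale counts and pattern
    frequencies are computed once and pooled cumulatively, which makes the
    full curve barely more expensive than the single largest scale.
    """
    x = _as_series(x)
    se = np.full(cfg.tau_max, np.nan)
    pe = np.full(cfg.tau_max, np.nan)
    if cfg.variant == "offset_composite":
        for tau in range(1, cfg.tau_max + 1):
            se[tau - 1] = _try_entropy(rcmse, x, tau, cfg)
            pe[tau - 1] = _try_entropy(rcmpe, x, tau, cfg)
        return se, pe

    r = cfg.r_coef * x.std()
    counts: list[tuple[int, int]] = []
    freqs: list[np.ndarray] = []
    for tau in range(1, cfg.tau_max + 1):
        y = coarse_grain(x, tau) if tau <= len(x) else np.empty(0)
        if len(y) > cfg.m_se + 1:
            counts.append(sample_entropy_counts(y, cfg.m_se, r))
            try:
                se[tau - 1] = _rcmse_from_counts(counts)
            except UndefinedEntropyError:
                pass
        if len(y) >= (cfg.m_pe - 1) * cfg.delay + 1:
            freqs.append(permutation_frequencies(y, cfg.m_pe, cfg.delay))
            if len(freqs) == tau:
                pe[tau - 1] = _shannon(np.mean(freqs, axis=0))
    return se, pe


def _try_entropy(fn, x, tau, cfg) -> float:
    try:
        return fn(x, tau, cfg)
    except (ValueError, UndefinedEntropyError):
        return math.nan
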