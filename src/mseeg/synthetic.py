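"""Synthetic two-group EEG-like cohorts with a scale-targeted complexity contrast.

Generates resting-state-like multichannel recordings for two groups
(healthy controls, HC, and a major-depressive-disorder group, MDD) so the
whole feature-extraction / classification / scale-analysis pipeline can be
exercised and calibrated without any real recordings.

Generative model, per channel and subject
-----------------------------------------
Each channel is an independent mixture of a smooth autoregressive background
and an irregular noise component::

    x = (1 - beta) * AR(1)(phi ~ 0.9)  +  beta * n(t)

where both components are standardised to unit variance and ``beta`` is the
irregularity weight.  The groups differ only in ``beta``:
``beta_MDD - beta_HC = 0.2 * effect_size``.  The noise component ``n(t)``
is band-limited around the effective Nyquist frequency of the target
coarse-graining scale, ``fs / (2 * effect_scale)``: block-averaging at
scales up to ``effect_scale`` retains it, while coarser scales average it
away.  The between-group entropy contrast therefore grows with scale up
to ``effect_scale`` and fades beyond it, emulating a coarse-scale-specific
complexity elevation whose optimal scale is known by construction.  For
``effect_scale == 1`` the component is plain white noise.

Channels are generated independently (no volume-conduction model); the AR
coefficient is jittered per subject (sd 0.02) so subjects are exchangeable
but not identical.  Everything is a pure function of the cohort
specification: the same :class:`CohortSpec` always yields a bit-identical
cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "ELECTRODES_10_20",
    "CohortSpec",
    "generate_reference_signal",
    "generate_subject",
    "generate_cohort",
    "write_cohort_csv",
]

#: The 19 scalp electrodes of the international 10-20 system, fixed order.
ELECTRODES_10_20 = (
    "Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5", "Fz",
    "Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6", "Cz", "Pz",
)

_AR_PHI = 0.9
_PHI_JITTER_SD = 0.02
_BETA_HC = 0.2
_BETA_STEP = 0.2  # beta_MDD - beta_HC per unit effect_size


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-group cohort.

    ``effect_scale`` is the coarse-graining scale at which the group
    complexity contrast is strongest by construction; ``effect_size`` is a
    dimensionless contrast in the generative mixing weight (0 disables the
    group difference entirely).
    """

    n_hc: int = 30
    n_mdd: int = 34
    n_channels: int = 19
    fs: float = 256.0
    duration: float = 300.0
    effect_scale: int = 3
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_mdd < 1:
            raise ValueError("group sizes must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 1 <= self.effect_scale <= 10:
            raise ValueError("effect_scale must lie in [1, 10]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return ELECTRODES_10_20[: self.n_channels] if self.n_channels <= 19 \
            else ELECTRODES_10_20 + tuple(
                f"X{i}" for i in range(self.n_channels - 19))


def _standardise(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-variance AR(1) series, stationary start, burn-in discarded."""
    w = rng.standard_normal(n + 200)
    x = sps.lfilter([1.0], [1.0, -phi], w)[200:]
    return _standardise(x)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                effect_scale: int) -> np.ndarray:
    """Unit-variance noise centred on fs / (2 * effect_scale).

    Straddling the effective Nyquist frequency of the target scale makes
    the component maximally irregular for the coarse series right at that
    scale, while coarser block means average it away — which is what pins
    the group contrast to ``effect_scale``.  At scale 1 plain white noise
    is the natural choice (every frequency is "at" scale 1).
    """
    w = rng.standard_normal(n)
    if effect_scale == 1:
        return _standardise(w)
    centre = fs / (2.0 * effect_scale)
    sos = sps.butter(4, [0.9 * centre, 1.1 * centre], btype="bandpass",
                     fs=fs, output="sos")
    return _standardise(sps.sosfiltfilt(sos, w))


def generate_reference_signal(kind: str, n: int, seed: int) -> np.ndarray:
    """Reference series with known entropy behaviour, for validation.

    ``white``     iid standard Gaussian noise (population variance 1);
    ``pink``      Gaussian noise with a 1/f amplitude spectrum, standardised
                  to unit sample variance;
    ``periodic``  a pure sinusoid (period 64 samples, seed-dependent phase),
                  unit sample variance.
    """
    if n < 100:
        raise ValueError(f"n must be >= 100, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "white":
        return rng.standard_normal(n)
    if kind == "pink":
        w = rng.standard_normal(n)
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n)
        f[0] = f[1]  # leave DC finite; removed by standardisation anyway
        spec /= np.sqrt(f)
        return _standardise(np.fft.irfft(spec, n))
    if kind == "periodic":
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n)
        return _standardise(np.sin(2 * np.pi * t / 64.0 + phase))
    raise ValueError(f"unknown reference-signal kind {kind!r}")


def _subject_beta(group: str, spec: CohortSpec) -> float:
    if group == "HC":
        return _BETA_HC
    if group == "MDD":
        return _BETA_HC + _BETA_STEP * spec.effect_size
    raise ValueError(f"group must be 'HC' or 'MDD', got {group!r}")


def generate_subject(group: str, spec: CohortSpec, subject_seed: int):
    """One synthetic recording (channels x samples) for ``group``.

    Returns an :class:`mseeg.preprocessing.EEGRecording`.  Deterministic in
    ``(group, spec, subject_seed)``; with ``effect_size == 0`` the HC and
    MDD generative distributions are identical.
    """
    from .preprocessing import EEGRecording  # local import avoids a cycle

    beta = _subject_beta(group, spec)
    rng = np.random.default_rng(subject_seed)
    n = spec.n_samples
    phi = float(np.clip(_AR_PHI + rng.normal(0.0, _PHI_JITTER_SD),
                        0.0, 0.995))
    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        ar = _ar1(rng, n, phi)
        noise = _band_noise(rng, n, spec.fs, spec.effect_scale)
        data[ch] = _standardise((1.0 - beta) * ar + beta * noise)
    return EEGRecording(
        data=data,
        fs=spec.fs,
        channel_names=list(spec.channel_names),
        subject_id=f"{group.lower()}{subject_seed:010d}",
        group=group,
    )


def _subject_seeds(spec: CohortSpec) -> list[int]:
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_hc + spec.n_mdd)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def generate_cohort(spec: CohortSpec) -> list:
    """All ``n_hc + n_mdd`` recordings of the cohort (HC first).

    Per-subject seeds are derived deterministically from ``spec.seed``, so
    the cohort is a pure function of the spec.
    """
    seeds = _subject_seeds(spec)
    cohort = []
    for i in range(spec.n_hc):
        cohort.append(generate_subject("HC", spec, seeds[i]))
    for i in range(spec.n_mdd):
        cohort.append(generate_subject("MDD", spec, seeds[spec.n_hc + i]))
    for idx, rec in enumerate(cohort):
        rec.subject_id = f"S{idx:03d}"
    return cohort


def write_cohort_csv(cohort: list, directory: str | Path,
                     spec: CohortSpec | None = None) -> Path:
    """Write a cohort as one CSV matrix (rows = channels) per subject.

    Alongside each matrix a ``<subject>.json`` sidecar stores the sampling
    rate and channel labels, and a ``manifest.json`` lists subject ids and
    group labels (plus the generating spec when given).  Returns the
    manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        stem = directory / rec.subject_id
        np.savetxt(f"{stem}.csv", rec.data, delimiter=",")
        with open(f"{stem}.json", "w") as fh:
            json.dump({"fs": rec.fs, "channel_names": rec.channel_names,
                       "subject_id": rec.subject_id, "group": rec.group},
                      fh, indent=1)
        entries.append({"subject_id": rec.subject_id, "group": rec.group,
                        "file": f"{rec.subject_id}.csv"})
    manifest = {"subjects": entries}
    if spec is not None:
        manifest["spec"] = {k: getattr(spec, k) for k in (
            "n_hc", "n_mdd", "n_channels", "fs", "duration",
            "effect_scale", "effect_size", "seed")}
    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
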