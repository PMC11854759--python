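"""Per-scale entropy feature matrices: epochs x (RCMSE block + RCMPE block).

Each epoch contributes one row per temporal scale tau: the RCMSE of every
channel followed by the RCMPE of every channel, in the fixed electrode
order.  One matrix is built per scale; models are trained per scale, never
across scales.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import EntropyConfig, entropy_curve, rcmpe, rcmse
from .preprocessing import Epoch

__all__ = ["FeatureMatrix", "extract_features", "extract_feature_curves",
           "write_feature_matrix", "read_feature_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Entropy features of a set of epochs at one temporal scale."""

    X: np.ndarray                  # epochs x (2 * n_channels)
    y: np.ndarray                  # group label per epoch ("HC" / "MDD")
    subject_ids: np.ndarray        # per-epoch provenance
    scale: int
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if not (len(self.X) == len(self.y) == len(self.subject_ids)):
            raise ValueError("X, y and subject_ids must have equal length")
        if self.X.ndim != 2 or (len(self.X) and
                                self.X.shape[1] != len(self.column_names)):
            raise ValueError("X shape inconsistent with column names")

    @property
    def n_epochs(self) -> int:
        return len(self.X)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.y)
        return df


def _safe(fn, x, tau, cfg) -> float:
    try:
        return fn(x, tau, cfg)
    except Exception:
        return np.nan


def _feature_columns(channel_names: list[str]) -> list[str]:
    return ([f"{ch}_RCMSE" for ch in channel_names]
            + [f"{ch}_RCMPE" for ch in channel_names])


def _check_channels(epochs: list[Epoch]) -> list[str]:
    if not epochs:
        raise ValueError("no epochs given")
    names = list(epochs[0].channel_names)
    for e in epochs[1:]:
        if list(e.channel_names) != names:
            raise ValueError("epochs have inconsistent channel sets")
    return names


def extract_features(epochs: list[Epoch], tau: int,
                     cfg: EntropyConfig = EntropyConfig()) -> FeatureMatrix:
    """Entropy feature matrix of ``epochs`` at scale ``tau``.

    Rows with any undefined entropy value are dropped (and counted in the
    log) rather than imputed.
    """
    if not 1 <= tau <= cfg.tau_max:
        raise ValueError(f"tau={tau} outside [1, {cfg.tau_max}]")
    names = _check_channels(epochs)
    rows, y, sids = [], [], []
    dropped = 0
    for ep in epochs:
        se_row, pe_row = [], []
        for ch in range(ep.data.shape[0]):
            x = ep.data[ch]
            se_row.append(_safe(rcmse, x, tau, cfg))
            pe_row.append(_safe(rcmpe, x, tau, cfg))
        row = np.array(se_row + pe_row, dtype=float)
        if np.isfinite(row).all():
            rows.append(row)
            y.append(ep.group)
            sids.append(ep.subject_id)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d epoch(s) with undefined entropy at tau=%d",
                    dropped, tau)
    X = np.array(rows) if rows else np.empty((0, 2 * len(names)))
    return FeatureMatrix(X, np.array(y, dtype=object),
                         np.array(sids, dtype=object), tau,
                         _feature_columns(names))


def extract_feature_curves(epochs: list[Epoch],
                           cfg: EntropyConfig = EntropyConfig()
                           ) -> dict[int, FeatureMatrix]:
    """Feature matrices at every scale 1..cfg.tau_max, sharing one pass.

    Computes the full entropy curve of every epoch-channel once and slices
    it per scale, which is far cheaper than calling
    :func:`extract_features` per scale and yields identical values for the
    default (``cumulative``) variant.
    """
    names = _check_channels(epochs)
    n_ch = len(names)
    curves = np.full((len(epochs), n_ch, 2, cfg.tau_max), np.nan)
    for i, ep in enumerate(epochs):
        for ch in range(n_ch):
            se, pe = entropy_curve(ep.data[ch], cfg)
            curves[i, ch, 0] = se
            curves[i, ch, 1] = pe
    out: dict[int, FeatureMatrix] = {}
    for tau in range(1, cfg.tau_max + 1):
        block = curves[:, :, :, tau - 1]           # epochs x ch x 2
        X = np.concatenate([block[:, :, 0], block[:, :, 1]], axis=1)
        keep = np.isfinite(X).all(axis=1)
        if (~keep).any():
            logger.info("dropped %d epoch(s) with undefined entropy at "
                        "tau=%d", int((~keep).sum()), tau)
        out[tau] = FeatureMatrix(
            X[keep],
            np.array([epochs[j].group for j in np.flatnonzero(keep)],
                     dtype=object),
            np.array([epochs[j].subject_id for j in np.flatnonzero(keep)],
                     dtype=object),
            tau, _feature_columns(names))
    return out


def write_feature_matrix(fm: FeatureMatrix, path: str | Path,
                         extra_meta: dict | None = None) -> Path:
    """Write a feature matrix as CSV plus a ``.json`` sidecar (scale, columns)."""
    path = Path(path)
    # %.17g keeps the round-trip lossless for float64
    fm.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    meta = {"scale": fm.scale, "column_names": fm.column_names}
    if extra_meta:
        meta.update(extra_meta)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Inverse of :func:`write_feature_matrix` (lossless round-trip)."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"feature table {path} missing column {col!r}")
    cols = meta["column_names"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns {missing}")
    X = df[cols].to_numpy(dtype=float) if len(df) else \
        np.empty((0, len(cols)))
    return FeatureMatrix(X, df["group"].to_numpy(dtype=object),
                         df["subject_id"].to_numpy(dtype=object),
                         int(meta["scale"]), list(cols))
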