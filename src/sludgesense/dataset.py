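"""Windowed supervised datasets for the soft sensor.

The estimator maps the ``lookback`` most recent measurements of the
observable channels (X3, X4, X5) to the current value of the unmeasured
substrates (X1, X2): sample ``j`` has inputs ``rows[j-lookback+1 .. j]`` and
target ``row[j]`` (concurrent soft sensing).  All channels are min-max
normalized to [0, 1]; the scaler is fitted on the training rows only and is
required to invert predictions back to mg/L.

Splits are chronological: the leading ``n_trainval`` rows are divided
80/20 into training and validation blocks, the remaining rows form the
held-out test block (canonically 3600 / 900 / 520 out of 5020).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DatasetConfig

__all__ = [
    "INPUT_CHANNELS",
    "TARGET_CHANNELS",
    "ScalingParams",
    "WindowedDataset",
    "fit_scaler",
    "normalize",
    "denormalize",
    "make_windows",
    "split_dataset",
    "apply_measurement_noise",
    "build_datasets",
]

logger = logging.getLogger(__name__)

INPUT_CHANNELS = ["X3", "X4", "X5"]
TARGET_CHANNELS = ["X1", "X2"]


@dataclass
class ScalingParams:
    """Per-channel min/max of the fitted (training) data."""

    channels: list[str]
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)

    def to_json(self) -> dict:
        return {c: {"min": float(lo), "max": float(hi)}
                for c, lo, hi in zip(self.channels, self.minimum, self.maximum)}

    @classmethod
    def from_json(cls, d: dict) -> "ScalingParams":
        channels = list(d)
        return cls(channels,
                   np.array([d[c]["min"] for c in channels]),
                   np.array([d[c]["max"] for c in channels]))


def _as_2d(data, channels: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        channels = channels or list(data.columns)
        return data[channels].to_numpy(dtype=float), channels
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    channels = channels or [f"ch{i}" for i in range(arr.shape[1])]
    return arr, channels


def fit_scaler(data, channels: list[str] | None = None) -> ScalingParams:
    """Per-channel min/max; rejects constant channels by name."""
    arr, channels = _as_2d(data, channels)
    if arr.shape[0] < 2:
        raise ValueError("fit_scaler requires at least 2 rows")
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    constant = [c for c, l, h in zip(channels, lo, hi) if not h > l]
    if constant:
        raise ValueError(f"constant channel(s) cannot be scaled: {constant}")
    return ScalingParams(channels, lo, hi)


def normalize(data, scaler: ScalingParams):
    """Map ``x -> (x - min) / (max - min)`` channel-wise.

    Values outside the fitted range pass through linearly (they land outside
    [0, 1]); a warning is logged when that happens.
    """
    arr, channels = _as_2d(data, getattr(data, "columns", None) is not None
                           and list(data.columns) or scaler.channels)
    if list(channels) != list(scaler.channels):
        raise ValueError(
            f"channel mismatch: data has {list(channels)}, "
            f"scaler was fitted on {scaler.channels}")
    if arr.shape[-1] != len(scaler.channels):
        raise ValueError("channel count mismatch with scaler")
    out = (arr - scaler.minimum) / (scaler.maximum - scaler.minimum)
    n_out = int(np.sum((out < 0.0) | (out > 1.0)))
    if n_out:
        logger.warning("normalize: %d value(s) outside the fitted range "
                       "mapped outside [0, 1]", n_out)
    if isinstance(data, pd.DataFrame):
        return pd.DataFrame(out, index=data.index, columns=channels)
    return out


def denormalize(data, scaler: ScalingParams):
    """Exact inverse of :func:`normalize`."""
    arr = np.asarray(data, dtype=float)
    if arr.shape[-1] != len(scaler.channels):
        raise ValueError("channel count mismatch with scaler")
    return arr * (scaler.maximum - scaler.minimum) + scaler.minimum


@dataclass
class WindowedDataset:
    """Normalized (window, target) pairs plus the scalers to invert them."""

    inputs: np.ndarray            # (n_samples, lookback, n_input_channels)
    targets: np.ndarray           # (n_samples, n_target_channels)
    lookback: int
    scaler_in: ScalingParams
    scaler_out: ScalingParams
    index_map: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_samples(self) -> int:
        return len(self.inputs)

    def subset(self, mask_or_idx) -> "WindowedDataset":
        return WindowedDataset(self.inputs[mask_or_idx],
                               self.targets[mask_or_idx], self.lookback,
                               self.scaler_in, self.scaler_out,
                               self.index_map[mask_or_idx])

    def flattened_inputs(self) -> np.ndarray:
        return self.inputs.reshape(self.n_samples, -1)

    def export(self, directory) -> None:
        """Write ``inputs.csv`` (flattened windows), ``targets.csv`` and
        ``scaler.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        L = self.lookback
        header = [f"{c.lower()}_t{-(L - 1 - k) or ''}"
                  for k in range(L) for c in self.scaler_in.channels]
        pd.DataFrame(self.flattened_inputs(), columns=header).to_csv(
            directory / "inputs.csv", index=False)
        pd.DataFrame(self.targets,
                     columns=[c.lower() for c in self.scaler_out.channels]
                     ).to_csv(directory / "targets.csv", index=False)
        (directory / "scaler.json").write_text(json.dumps(
            {"inputs": self.scaler_in.to_json(),
             "outputs": self.scaler_out.to_json()}, indent=2))


def make_windows(rows: pd.DataFrame, lookback: int = 7,
                 scaler_in: ScalingParams | None = None,
                 scaler_out: ScalingParams | None = None) -> WindowedDataset:
    """Sliding windows over a trajectory frame.

    ``rows`` must contain the input channels (X3, X4, X5) and target channels
    (X1, X2) in original units; scalers default to a fit over all of ``rows``
    (pass training-only scalers to avoid leakage).  Sample ``j`` (for ``j``
    from ``lookback-1`` to ``n_rows-1``) has inputs ending at row ``j`` and
    target at row ``j``; ``index_map`` records ``j``.
    """
    n_rows = len(rows)
    if n_rows < lookback:
        raise ValueError(f"need at least lookback={lookback} rows, got {n_rows}")
    scaler_in = scaler_in or fit_scaler(rows[INPUT_CHANNELS])
    scaler_out = scaler_out or fit_scaler(rows[TARGET_CHANNELS])
    x = normalize(rows[INPUT_CHANNELS], scaler_in).to_numpy()
    y = normalize(rows[TARGET_CHANNELS], scaler_out).to_numpy()
    idx = np.arange(lookback - 1, n_rows)
    windows = np.stack([x[j - lookback + 1: j + 1] for j in idx])
    return WindowedDataset(windows.astype(np.float64), y[idx], lookback,
                           scaler_in, scaler_out, idx)


def split_dataset(n_rows: int, n_trainval: int = 4500,
                  train_fraction: float = 0.8):
    """Chronological (train, validation, test) row ranges.

    The leading ``n_trainval`` rows are split ``train_fraction`` /
    ``1 - train_fraction`` in time order; the remainder is the test block.
    Returns three ``range`` objects that are disjoint, ordered and exhaustive.
    """
    if n_rows <= n_trainval:
        raise ValueError(f"need more than n_trainval={n_trainval} rows "
                         f"to form a test block, got {n_rows}")
    n_train = int(round(train_fraction * n_trainval))
    if n_train < 2 or n_trainval - n_train < 1:
        raise ValueError("degenerate split")
    return (range(0, n_train), range(n_train, n_trainval),
            range(n_trainval, n_rows))


def apply_measurement_noise(rows: pd.DataFrame, rel_sd: float,
                            seed: int) -> pd.DataFrame:
    """Multiplicative Gaussian measurement noise on the recorded states.

    Emulates sensor error on the dataset: each state channel is scaled by
    ``1 + rel_sd * eps`` element-wise, clipped at zero.  The trajectory
    itself (plant physics) is untouched; only the recorded copies change.
    """
    if rel_sd < 0:
        raise ValueError("rel_sd must be >= 0")
    out = rows.copy()
    if rel_sd == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = [c for c in ("X1", "X2", "X3", "X4", "X5") if c in out.columns]
    values = out[cols].to_numpy(dtype=float)
    noisy = values * (1.0 + rel_sd * rng.standard_normal(values.shape))
    out[cols] = np.maximum(noisy, 0.0)
    return out


def build_datasets(rows: pd.DataFrame, cfg: DatasetConfig):
    """Split a (noisy) state frame and window it without leakage.

    Returns ``(train, val, test)`` :class:`WindowedDataset` objects sharing
    scalers fitted on the training rows only.  Training samples use only
    rows inside the training block; validation/test windows may reach back
    into earlier rows for their *inputs* (those are measured channels), but
    their targets lie strictly inside their own block.
    """
    tr, va, te = split_dataset(len(rows), cfg.n_trainval, cfg.train_fraction)
    scaler_in = fit_scaler(rows.iloc[tr.start: tr.stop][INPUT_CHANNELS])
    scaler_out = fit_scaler(rows.iloc[tr.start: tr.stop][TARGET_CHANNELS])
    full = make_windows(rows, cfg.lookback, scaler_in, scaler_out)
    j = full.index_map
    train = full.subset((j >= tr.start + cfg.lookback - 1) & (j < tr.stop))
    val = full.subset((j >= va.start) & (j < va.stop))
    test = full.subset((j >= te.start) & (j < te.stop))
    return train, val, test
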