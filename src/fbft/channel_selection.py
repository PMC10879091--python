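"""Correlation-based EEG channel selection.

Multi-channel EEG is highly redundant: neighbouring electrodes record
overlapping cortical activity, so feeding every channel to a classifier
mostly multiplies cost, not information.  The selection rule implemented
here scores each channel by its mean absolute Pearson correlation with all
channels (the column mean of the absolute correlation matrix, mCC) and
keeps the channels with the *lowest* scores — the ones carrying the most
unique signal.

The diagonal (self-correlation, 1) is included in the column mean.  This
shifts every channel's score equally by 1/n and therefore never changes
the ranking; it matches reading the rule literally as "the mean of each
column".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .signal import Signal

__all__ = ["CorrelationSummary", "pearson_abs", "correlation_summary", "select_channels"]


@dataclass(frozen=True)
class CorrelationSummary:
    """Absolute Pearson correlation matrix with per-channel mean scores.

    ``matrix[i, j]`` is ``|r|`` between channels i and j; ``mcc[i]`` is the
    arithmetic mean of column i (diagonal included); ``channel_names``
    aligns labels to rows/columns.
    """

    matrix: npt.NDArray[np.float64]
    mcc: npt.NDArray[np.float64]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "mcc", np.asarray(self.mcc, dtype=float))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if len(self.channel_names) != m.shape[0]:
            raise ValueError("channel_names length must match matrix size")


def pearson_abs(x1: npt.ArrayLike, x2: npt.ArrayLike) -> float:
    """Absolute Pearson correlation |r| between two equal-length sequences.

    Computed as the mean-centred cross-product over the product of the
    root sums of squares.  A constant sequence makes r a 0/0 form; such
    pairs return 0 with a warning, so dead channels rank as maximally
    unique and surface for review instead of crashing a batch.
    """
    a = np.asarray(x1, dtype=float).ravel()
    b = np.asarray(x2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        warnings.warn(
            "correlation undefined for a constant sequence; returning 0",
            stacklevel=2,
        )
        return 0.0
    return float(min(abs((da * db).sum() / denom), 1.0))


def correlation_summary(signal: Signal) -> CorrelationSummary:
    """Pairwise |r| matrix and per-channel mean correlation coefficients."""
    if signal.n_channels < 2:
        raise ValueError("correlation summary needs at least 2 channels")
    n = signal.n_channels
    matrix = np.empty((n, n))
    for i in range(n):
        matrix[i, i] = pearson_abs(signal.samples[i], signal.samples[i])
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = pearson_abs(
                signal.samples[i], signal.samples[j]
            )
    return CorrelationSummary(
        matrix=matrix, mcc=matrix.mean(axis=0), channel_names=signal.channel_names
    )


def select_channels(summary: CorrelationSummary, k: int) -> list[str]:
    """The k channel names with the smallest mCC, in ascending-mCC order.

    Ties keep the original channel order (stable sort).
    """
    n = len(summary.channel_names)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.argsort(summary.mcc, kind="stable")
    return [summary.channel_names[i] for i in order[:k]]
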