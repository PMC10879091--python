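"""Core signal container and windowing.

A :class:`Signal` is a uniformly sampled multi-channel time series — the
common currency every reader, generator and transform in this package
speaks.  Channels are rows, samples are columns, and time is measured in
seconds from the start of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt

__all__ = ["Signal", "SegmentSpec", "clean_nans", "segment"]


class EmptySignalError(ValueError):
    """Raised when an operation would produce a signal with no samples."""


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled multi-channel time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``; amplitude in native
        units (µV for EEG, arbitrary units for audio).
    fs
        Sampling rate in Hz; must be positive.
    channel_names
        Ordered, unique channel labels, one per row of ``samples``.
    t0
        Start offset of the recording in seconds (default 0).
    """

    samples: npt.NDArray[np.floating]
    fs: float
    channel_names: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if arr.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        if arr.shape[1] < 1:
            raise EmptySignalError("signal must contain at least one sample")
        if len(self.channel_names) != arr.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> npt.NDArray[np.float64]:
        """Per-sample time stamps in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> npt.NDArray[np.floating]:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.samples[idx]

    def pick(self, names: list[str] | tuple[str, ...]) -> "Signal":
        """Sub-signal restricted to the given channels, in the given order."""
        rows = [self.channel_names.index(n) if n in self.channel_names else -1 for n in names]
        missing = [n for n, r in zip(names, rows) if r < 0]
        if missing:
            raise KeyError(f"unknown channels: {missing}")
        return replace(self, samples=self.samples[rows], channel_names=tuple(names))


@dataclass(frozen=True)
class SegmentSpec:
    """Window length / overlap contract for slicing a recording.

    ``window_s`` must be positive and ``overlap_s`` must satisfy
    ``0 <= overlap_s < window_s`` so that consecutive windows advance.
    """

    window_s: float
    overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError(f"window_s must be positive, got {self.window_s}")
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError(
                f"overlap_s must satisfy 0 <= overlap < window, got "
                f"overlap={self.overlap_s}, window={self.window_s}"
            )

    @property
    def step_s(self) -> float:
        return self.window_s - self.overlap_s


def clean_nans(signal: Signal, policy: str = "drop_samples") -> Signal:
    """Remove non-finite values from a signal.

    ``drop_samples`` deletes every time index at which *any* channel is
    non-finite (the time axis is re-indexed, preserving fs).  ``interpolate``
    fills gaps per channel by linear interpolation between the nearest
    finite neighbours, extending edge values at the boundaries.

    Raises
    ------
    EmptySignalError
        If every sample is non-finite and nothing remains.
    """
    if policy not in ("drop_samples", "interpolate"):
        raise ValueError(f"unknown policy {policy!r}")
    x = signal.samples
    finite = np.isfinite(x)
    if finite.all():
        return signal
    if policy == "drop_samples":
        keep = finite.all(axis=0)
        if not keep.any():
            raise EmptySignalError("all samples non-finite after cleaning")
        return replace(signal, samples=x[:, keep])
    out = x.copy()
    idx = np.arange(signal.n_samples)
    for ch in range(signal.n_channels):
        good = finite[ch]
        if not good.any():
            raise EmptySignalError(
                f"channel {signal.channel_names[ch]!r} has no finite samples"
            )
        if not good.all():
            # np.interp clamps to edge values outside the finite support
            out[ch] = np.interp(idx, idx[good], out[ch, good])
    return replace(signal, samples=out)


def segment(signal: Signal, spec: SegmentSpec) -> list[Signal]:
    """Slice a signal into fixed-length overlapping windows.

    Window ``k`` covers the half-open interval
    ``[k * step, k * step + window)`` in seconds; every window has exactly
    ``round(window_s * fs)`` samples and the trailing partial window is
    discarded.  A window longer than the record yields an empty list with a
    warning rather than an error so batch runs can skip short records.
    """
    win = int(round(spec.window_s * signal.fs))
    step = spec.step_s * signal.fs
    if win > signal.n_samples:
        warnings.warn(
            f"window of {win} samples exceeds signal length {signal.n_samples}; "
            "no windows produced",
            stacklevel=2,
        )
        return []
    out: list[Signal] = []
    k = 0
    while True:
        start = int(round(k * step))
        if start + win > signal.n_samples:
            break
        out.append(
            replace(
                signal,
                samples=signal.samples[:, start : start + win],
                t0=signal.t0 + start / signal.fs,
            )
        )
        k += 1
    return out
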