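"""The forward-backward Fourier transform (FBFT).

For every time index ``u`` the transform pairs two zero-padded FFT
magnitude spectra — the *forward* spectrum of the prefix ``x[0:u+1]`` and
the *backward* spectrum of the suffix ``x[u:]`` — and keeps their
element-wise minimum:

.. math::

    X[f, u] = \\min\\big( |\\mathrm{FFT}(x[0:u+1])|_f,\\;
                          |\\mathrm{FFT}(x[u:])|_f \\big)

A frequency component shows up in the minimum only while *both* the
prefix and the suffix contain it, i.e. only inside its interval of
activity.  That is what makes the minimum a time-localiser: a tone active
on ``[a, b)`` contributes a ridge at its frequency for ``u`` between ``a``
and ``b`` and is suppressed outside, without any windowing trade-off.

Both subarrays are zero-padded to one common length before the FFT so that
every column shares a single frequency grid.  The minimum is taken on raw
magnitudes (the growth of spectral magnitude with subarray length is part
of the transform's shape); an opt-in per-length normalisation is provided
for visualisation.

Complexity is O(n) FFTs of the padded length per window, so keeping
windows to a few thousand samples keeps desk-scale runtimes in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import numpy.typing as npt

from .signal import Signal

__all__ = [
    "TFMap",
    "prefix_spectra",
    "suffix_spectra",
    "fbft",
    "fbft_reference",
    "fbft_signal",
    "ridge_frequency",
    "default_pad_len",
]


@dataclass(frozen=True)
class TFMap:
    """Non-negative magnitude over a frequency x time grid.

    ``magnitude`` has shape ``(n_freq_bins, n_time_points)``; ``freqs`` is
    the ascending frequency axis in Hz (one-sided, DC first), ``times`` the
    ascending time axis in seconds.  ``meta`` records the transform name
    and its parameters.
    """

    magnitude: npt.NDArray[np.float64]
    freqs: npt.NDArray[np.float64]
    times: npt.NDArray[np.float64]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "times", times)
        if mag.ndim != 2:
            raise ValueError("magnitude must be 2-D (freq x time)")
        if mag.shape != (freqs.size, times.size):
            raise ValueError(
                f"magnitude shape {mag.shape} does not match axes "
                f"({freqs.size} freqs, {times.size} times)"
            )
        if not np.isfinite(mag).all() or (mag < 0).any():
            raise ValueError("magnitudes must be finite and non-negative")
        if freqs.size > 1 and not (np.diff(freqs) > 0).all():
            raise ValueError("freqs must be strictly increasing")
        if times.size > 1 and not (np.diff(times) > 0).all():
            raise ValueError("times must be strictly increasing")


def default_pad_len(n_samples: int) -> int:
    """Smallest power of two >= 2 * n_samples.

    Zero-padding every subarray to one common power-of-two length puts all
    columns on the same frequency grid and keeps the FFTs fast.
    """
    return 1 << int(np.ceil(np.log2(max(2 * n_samples, 2))))


def _u_grid(n: int, stride: int) -> npt.NDArray[np.intp]:
    """Evaluated time indices: 0, stride, 2*stride, ..., always ending at n-1."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    grid = np.arange(0, n, stride)
    if grid[-1] != n - 1:
        grid = np.append(grid, n - 1)
    return grid


def _check_pad(n: int, pad_len: int) -> None:
    if pad_len < n:
        raise ValueError(
            f"pad_len {pad_len} shorter than signal length {n}: zero padding "
            "must extend the signal"
        )


def prefix_spectra(
    x: npt.ArrayLike, pad_len: int, stride: int = 1
) -> npt.NDArray[np.float64]:
    """One-sided |FFT| of each zero-padded prefix ``x[0:u+1]``.

    Column c holds the spectrum for the c-th evaluated index u (the grid is
    0, stride, 2*stride, ... capped at and always including n-1).
    """
    x = np.asarray(x, dtype=float).ravel()
    _check_pad(x.size, pad_len)
    grid = _u_grid(x.size, stride)
    out = np.empty((pad_len // 2 + 1, grid.size))
    for c, u in enumerate(grid):
        out[:, c] = np.abs(np.fft.rfft(x[: u + 1], n=pad_len))
    return out


def suffix_spectra(
    x: npt.ArrayLike, pad_len: int, stride: int = 1
) -> npt.NDArray[np.float64]:
    """One-sided |FFT| of each zero-padded suffix ``x[u:]``.

    Column c is aligned to the same evaluated index u as
    :func:`prefix_spectra`, so column c holds the spectrum of ``x[u:]`` —
    sample u belongs to both the prefix and the suffix of its column.
    """
    x = np.asarray(x, dtype=float).ravel()
    _check_pad(x.size, pad_len)
    grid = _u_grid(x.size, stride)
    out = np.empty((pad_len // 2 + 1, grid.size))
    for c, u in enumerate(grid):
        out[:, c] = np.abs(np.fft.rfft(x[u:], n=pad_len))
    return out


def fbft(
    x: npt.ArrayLike,
    fs: float,
    pad_len: int | None = None,
    stride: int = 1,
    normalize: bool = False,
) -> TFMap:
    """Forward-backward Fourier transform of a single-channel signal.

    Parameters
    ----------
    x
        Real-valued samples.
    fs
        Sampling rate in Hz.
    pad_len
        Common zero-padded FFT length; defaults to the smallest power of
        two >= 2 * len(x).  Must be >= len(x).
    stride
        Thins the evaluated time grid for long windows (default 1 = every
        sample); the final sample is always evaluated.
    normalize
        Divide each prefix/suffix spectrum by its subarray length before
        the minimum (visualisation aid; default off).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("fbft needs at least 2 samples")
    if pad_len is None:
        pad_len = default_pad_len(x.size)
    fwd = prefix_spectra(x, pad_len, stride)
    bwd = suffix_spectra(x, pad_len, stride)
    grid = _u_grid(x.size, stride)
    if normalize:
        fwd = fwd / (grid + 1)
        bwd = bwd / (x.size - grid)
    mag = np.minimum(fwd, bwd)
    return TFMap(
        magnitude=mag,
        freqs=np.fft.rfftfreq(pad_len, d=1.0 / fs),
        times=grid / fs,
        meta={
            "transform": "fbft",
            "pad_len": int(pad_len),
            "stride": int(stride),
            "normalize": bool(normalize),
            "fs": float(fs),
            "n_samples": int(x.size),
        },
    )


def fbft_reference(x: npt.ArrayLike, fs: float, pad_len: int | None = None) -> TFMap:
    """Literal list-based transcription of the FBFT procedure; the test oracle.

    Builds the forward list M of prefix FFTs, the backward list M1 of
    suffix FFTs taken from the end (``x[-u-1:]``), reverses M1 and takes
    the element-wise minimum of the magnitudes.  Always stride 1, no
    vectorisation; exists solely so the fast path can be proven equal to
    the written-out procedure.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("fbft needs at least 2 samples")
    if pad_len is None:
        pad_len = default_pad_len(x.size)
    _check_pad(x.size, pad_len)
    M = []
    for u in range(len(x)):
        H = x[: u + 1]
        M.append(np.fft.rfft(H, n=pad_len))
    M1 = []
    for u in range(len(x)):
        H1 = x[-u - 1 :]
        M1.append(np.fft.rfft(H1, n=pad_len))
    M1.reverse()
    min_values = [np.minimum(np.abs(a), np.abs(b)) for a, b in zip(M, M1)]
    return TFMap(
        magnitude=np.array(min_values).T,
        freqs=np.fft.rfftfreq(pad_len, d=1.0 / fs),
        times=np.arange(len(x)) / fs,
        meta={
            "transform": "fbft_reference",
            "pad_len": int(pad_len),
            "stride": 1,
            "normalize": False,
            "fs": float(fs),
            "n_samples": int(x.size),
        },
    )


def fbft_signal(signal: Signal, channel: str | None = None, **kwargs: Any) -> TFMap:
    """Convenience wrapper: FBFT of one channel of a :class:`Signal`."""
    if channel is None:
        if signal.n_channels != 1:
            raise ValueError("multi-channel signal: specify channel=")
        x = signal.samples[0]
    else:
        x = signal.channel(channel)
    return fbft(x, fs=signal.fs, **kwargs)


def ridge_frequency(
    tf: TFMap,
    t_start: float | None = None,
    t_end: float | None = None,
    top_k: int = 1,
) -> float | None | list[float]:
    """Dominant frequency of a TF map over a time interval.

    Averages the magnitude over all time columns falling in the half-open
    interval ``[t_start, t_end)`` (the whole axis when omitted), excludes
    the DC bin, and returns the frequency of the arg-max.  With
    ``top_k > 1`` the top-k peak frequencies by prominence are returned,
    strongest first.  An all-zero interval has no ridge and yields the
    sentinel ``None`` (or an empty list for top_k > 1).
    """
    t_start = tf.times[0] if t_start is None else t_start
    t_end = tf.times[-1] + np.finfo(float).eps if t_end is None else t_end
    mask = (tf.times >= t_start) & (tf.times < t_end)
    if not mask.any():
        raise ValueError(
            f"interval [{t_start}, {t_end}) does not intersect the time axis "
            f"[{tf.times[0]}, {tf.times[-1]}]"
        )
    profile = tf.magnitude[:, mask].mean(axis=1)
    profile = profile[1:]  # exclude DC
    freqs = tf.freqs[1:]
    if top_k == 1:
        if not profile.any():
            return None
        return float(freqs[int(np.argmax(profile))])
    from scipy.signal import find_peaks

    peaks, props = find_peaks(profile, prominence=0.0)
    if peaks.size == 0:
        return []
    order = np.argsort(props["prominences"])[::-1]
    return [float(freqs[p]) for p in peaks[order][:top_k]]
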