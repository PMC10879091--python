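"""Comparison time-frequency transforms on the common TFMap grid.

The transforms themselves (short-time Fourier spectrogram, continuous
wavelet scalogram, discrete wavelet band map, power spectrum) come from
scipy and PyWavelets; this module's job is the uniform adapter — every
method returns a :class:`~fbft.fbft_core.TFMap` with the same axis
conventions as the forward-backward transform so maps can be rendered and
compared side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import numpy.typing as npt
import pywt
from scipy import signal as sps

from .fbft_core import TFMap

__all__ = ["BaselineSpec", "baseline_tf", "BASELINE_METHODS"]

BASELINE_METHODS = ("stft", "cwt", "dwt", "power_spectrum")


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to run and with what parameters.

    stft: ``window_len`` samples per frame, ``hop`` samples between frames.
    cwt: ``wavelet`` family (continuous, default Morlet) and ``n_scales``
    log-spaced scales covering ``f_min``..fs/2.
    dwt: ``wavelet`` (discrete, default db4) and ``level`` decomposition
    depth (default: maximum usable for the data length).
    power_spectrum: no parameters (periodogram of the whole record).
    """

    method: str
    window_len: int = 256
    hop: int = 64
    wavelet: str | None = None
    n_scales: int = 64
    f_min: float = 1.0
    level: int | None = None

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {BASELINE_METHODS}"
            )
        if self.window_len < 2 or self.hop < 1:
            raise ValueError("stft needs window_len >= 2 and hop >= 1")
        if self.n_scales < 2:
            raise ValueError("cwt needs at least 2 scales")


def baseline_tf(x: npt.ArrayLike, fs: float, spec: BaselineSpec) -> TFMap:
    """Run the named baseline and adapt its output to a TFMap."""
    x = np.asarray(x, dtype=float).ravel()
    if spec.method == "stft":
        return _stft(x, fs, spec)
    if spec.method == "cwt":
        return _cwt(x, fs, spec)
    if spec.method == "dwt":
        return _dwt(x, fs, spec)
    return _power_spectrum(x, fs)


def _stft(x: np.ndarray, fs: float, spec: BaselineSpec) -> TFMap:
    win_len = min(spec.window_len, x.size)
    stft = sps.ShortTimeFFT(
        sps.windows.hann(win_len, sym=False),
        hop=spec.hop,
        fs=fs,
        scale_to="magnitude",
    )
    S = stft.stft(x)
    times = stft.t(x.size)
    # trim slide-in/out frames so every column is fully supported by data
    keep = (times >= 0) & (times <= x.size / fs)
    return TFMap(
        magnitude=np.abs(S[:, keep]),
        freqs=stft.f,
        times=times[keep],
        meta={"transform": "stft", "window_len": win_len, "hop": spec.hop, "fs": fs},
    )


def _cwt(x: np.ndarray, fs: float, spec: BaselineSpec) -> TFMap:
    wavelet = spec.wavelet or "morl"
    f_max = fs / 2
    freqs_wanted = np.geomspace(spec.f_min, f_max, spec.n_scales)
    center = pywt.central_frequency(wavelet)
    scales = center * fs / freqs_wanted  # scale2frequency inverted
    coeffs, freqs = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    order = np.argsort(freqs)
    return TFMap(
        magnitude=np.abs(coeffs)[order],
        freqs=freqs[order],
        times=np.arange(x.size) / fs,
        meta={"transform": "cwt", "wavelet": wavelet, "n_scales": spec.n_scales, "fs": fs},
    )


def _dwt(x: np.ndarray, fs: float, spec: BaselineSpec) -> TFMap:
    """Piecewise-constant time x band image, one row per decomposition level.

    A discrete wavelet decomposition is not naturally a dense TF grid; each
    level's coefficient magnitudes are held constant over that level's time
    support and the row is placed at the band's centre frequency.
    """
    wavelet = spec.wavelet or "db4"
    max_level = pywt.dwt_max_level(x.size, wavelet)
    if max_level < 1:
        raise ValueError(f"signal of {x.size} samples too short for dwt with {wavelet}")
    level = spec.level if spec.level is not None else max_level
    if not 1 <= level <= max_level:
        raise ValueError(f"level must be in [1, {max_level}], got {level}")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    # bands, coarse to fine: approx [0, fs/2^(L+1)], details [fs/2^(l+1), fs/2^l]
    rows, centers = [], []
    for i, c in enumerate(coeffs):
        if i == 0:
            lo, hi = 0.0, fs / 2 ** (level + 1)
        else:
            lvl = level - i + 1
            lo, hi = fs / 2 ** (lvl + 1), fs / 2**lvl
        centers.append(0.5 * (lo + hi))
        # hold each coefficient over its time support
        rows.append(np.repeat(np.abs(c), int(np.ceil(x.size / len(c))))[: x.size])
    order = np.argsort(centers)
    return TFMap(
        magnitude=np.vstack([rows[i] for i in order]),
        freqs=np.asarray(centers)[order],
        times=np.arange(x.size) / fs,
        meta={"transform": "dwt", "wavelet": wavelet, "level": level, "fs": fs},
    )


def _power_spectrum(x: np.ndarray, fs: float) -> TFMap:
    freqs, pxx = sps.periodogram(x, fs=fs)
    return TFMap(
        magnitude=pxx[:, np.newaxis],
        freqs=freqs,
        times=np.array([x.size / (2 * fs)]),  # single column at the record midpoint
        meta={"transform": "power_spectrum", "fs": fs},
    )
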