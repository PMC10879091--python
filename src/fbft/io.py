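"""Readers and writers normalising EDF, WAV and delimited text to :class:`Signal`.

EDF (European Data Format) carries polygraphic EEG, WAV carries heart-sound
audio, and delimited text covers consumer headband exports (one column per
channel, header row of channel names).  Text formats carry no sampling rate,
so ``fs`` must be supplied explicitly for them — it is never guessed.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import Signal

__all__ = ["read_signal", "write_csv"]

_FORMATS = ("edf", "csv", "wav")


class SignalFormatError(ValueError):
    """File parsed but its contents violate the format contract."""


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in _FORMATS:
        return ext
    raise ValueError(
        f"cannot infer format from {path.name!r}; pass format= one of {_FORMATS}"
    )


def read_signal(
    path: str | os.PathLike,
    format: str | None = None,
    *,
    fs: float | None = None,
    delimiter: str = ",",
) -> Signal:
    """Load a multi-channel recording from disk.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``edf``, ``csv``, ``wav``; inferred from the extension when
        omitted.
    fs
        Sampling rate in Hz — required for ``csv`` (the text format stores
        none), ignored for ``edf``/``wav`` whose metadata carries it.
    delimiter
        Column separator for delimited text (default comma).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read signal file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "wav":
        return _read_wav(path)
    if fmt == "csv":
        if fs is None:
            raise ValueError(
                f"reading {path.name}: delimited text carries no sampling rate; "
                "fs must be supplied explicitly"
            )
        return _read_csv(path, fs=fs, delimiter=delimiter)
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def _read_edf(path: Path) -> Signal:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for malformed files
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    return Signal(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
    )


def _read_wav(path: Path) -> Signal:
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[np.newaxis, :]
    else:  # wavfile returns (n_samples, n_channels)
        data = data.T
    names = tuple(f"audio{i}" for i in range(data.shape[0]))
    return Signal(samples=data, fs=float(rate), channel_names=names)


def _read_csv(path: Path, fs: float, delimiter: str) -> Signal:
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except pd.errors.ParserError as exc:
        raise SignalFormatError(f"{path}: ragged rows or malformed text: {exc}") from exc
    if frame.shape[1] < 1 or frame.shape[0] < 1:
        raise SignalFormatError(f"{path}: no data columns found")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise SignalFormatError(f"{path}: non-numeric columns {non_numeric}")
    return Signal(
        samples=frame.to_numpy(dtype=float).T,
        fs=float(fs),
        channel_names=tuple(str(c) for c in frame.columns),
    )


def write_csv(signal: Signal, path: str | os.PathLike, *, delimiter: str = ",") -> None:
    """Write a signal as delimited text, one column per channel.

    The sampling rate is not stored in the file; callers that round-trip
    through text must carry ``fs`` separately (e.g. the simulate command
    writes a JSON descriptor next to the csv).
    """
    frame = pd.DataFrame(signal.samples.T, columns=list(signal.channel_names))
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")
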