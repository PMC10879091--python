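import struct

import numpy as np
import pytest

from fbft import Signal, three_tone_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_tone():
    """The worked-example composite: 10/20/60 Hz in consecutive 1 s slots."""
    return three_tone_preset()


@pytest.fixture
def small_signal(rng):
    return Signal(rng.standard_normal((3, 200)), fs=100.0, channel_names=("a", "b", "c"))


def dft_mag_onesided(x, pad_len):
    """Independent O(n * pad_len) direct DFT magnitude oracle (one-sided)."""
    x = np.asarray(x, dtype=float)
    k = np.arange(pad_len // 2 + 1)
    m = np.arange(x.size)
    ker = np.exp(-2j * np.pi * np.outer(k, m) / pad_len)
    return np.abs(ker @ x)


def write_minimal_edf(path, samples, fs, channel_names):
    """Write a bare-bones single-record EDF file (int16, identity scaling).

    Enough of the format for round-trip reader tests; not a general writer.
    """
    samples = np.asarray(samples)
    ns = samples.shape[0]
    n_per_rec = samples.shape[1]
    dur = n_per_rec / fs

    def pad(s, n):
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2024 X X X", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad("1", 8),
            pad(f"{dur:g}", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        [pad(nm, 16) for nm in channel_names],
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(n_per_rec), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    body = np.round(samples).astype("<i2").tobytes()
    with open(path, "wb") as fh:
        fh.write(hdr)
        for f in fields:
            fh.write(b"".join(f))
        fh.write(body)
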