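"""Synthetic signal generators.

Two families of surrogate data drive development and testing without any
recorded data:

* **Composite tones** — sums of sinusoids, each switched on over its own
  time interval, emulating the worked example of a signal whose 10, 20 and
  60 Hz components occupy consecutive one-second intervals.  These give a
  time–frequency transform a known ground-truth ridge per interval.
* **Latent-mix EEG surrogates** — multi-channel recordings where every
  channel loads on one shared band-limited source plus independent noise,
  planting a known correlation structure for the channel-selection stage.

All randomness flows through one explicit seed; no global random state is
touched, and identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal import Signal

__all__ = [
    "ComponentSpec",
    "LatentMixSpec",
    "composite_signal",
    "correlated_eeg",
    "three_tone_preset",
    "eeg_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One sinusoidal component, active on the half-open interval [t_on, t_off).

    freq is in Hz, amp in arbitrary units, phase in radians.
    """

    freq: float
    amp: float = 1.0
    t_on: float = 0.0
    t_off: float = np.inf
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.freq < 0:
            raise ValueError(f"freq must be >= 0, got {self.freq}")
        if self.amp < 0:
            raise ValueError(f"amp must be >= 0, got {self.amp}")
        if not (0 <= self.t_on < self.t_off):
            raise ValueError(
                f"need 0 <= t_on < t_off, got t_on={self.t_on}, t_off={self.t_off}"
            )


@dataclass(frozen=True)
class LatentMixSpec:
    """Multi-channel surrogate: channel i = loadings[i] * g(t) + noise.

    ``g`` is a shared band-limited (0–40 Hz) unit-variance Gaussian source;
    each channel adds independent white Gaussian noise of sd ``noise_sd``.
    Channels with equal nonzero loadings are strongly correlated; a channel
    with loading 0 is independent of all others.
    """

    n_channels: int
    loadings: tuple[float, ...]
    noise_sd: float = 0.3
    fs: float = 256.0
    duration: float = 20.0
    seed: int = 0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", tuple(self.loadings))
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if len(self.loadings) != self.n_channels:
            raise ValueError(
                f"{len(self.loadings)} loadings for {self.n_channels} channels"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def composite_signal(
    components: list[ComponentSpec],
    fs: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "composite",
) -> Signal:
    """Sum of gated sinusoids plus optional Gaussian noise.

    The sample at time t is
    ``sum_k amp_k * sin(2*pi*freq_k*t + phase_k) * 1{t_on_k <= t < t_off_k}``
    with noise of the given standard deviation added when ``noise_sd > 0``.
    Every component must respect the Nyquist limit ``freq < fs / 2``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    for comp in components:
        if comp.freq >= fs / 2:
            raise ValueError(
                f"component at {comp.freq} Hz violates the Nyquist limit for fs={fs}"
            )
    t = np.arange(int(round(duration * fs))) / fs
    x = np.zeros_like(t)
    for comp in components:
        gate = (t >= comp.t_on) & (t < comp.t_off)
        x += comp.amp * np.sin(2 * np.pi * comp.freq * t + comp.phase) * gate
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return Signal(samples=x[np.newaxis, :], fs=fs, channel_names=(name,))


def correlated_eeg(spec: LatentMixSpec) -> Signal:
    """Multi-channel surrogate with planted correlation structure.

    The shared source is white Gaussian noise low-pass filtered to 0–40 Hz
    (zero-phase Butterworth) and rescaled to unit variance — an EEG-like
    spectrum without any claim of physiological realism.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    g = rng.standard_normal(n)
    cutoff = min(40.0, 0.45 * spec.fs)  # keep the filter valid for low fs
    sos = sps.butter(4, cutoff, btype="low", fs=spec.fs, output="sos")
    g = sps.sosfiltfilt(sos, g)
    g = g / g.std()
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, n))
    samples = np.asarray(spec.loadings)[:, np.newaxis] * g + noise
    names = spec.channel_names or tuple(f"ch{i}" for i in range(spec.n_channels))
    return Signal(samples=samples, fs=spec.fs, channel_names=names)


def three_tone_preset(seed: int = 0, noise_sd: float = 0.0) -> Signal:
    """The worked-example composite: 10, 20 and 60 Hz tones in consecutive 1 s slots.

    Amplitudes are 1, fs is 500 Hz and the record lasts 3 s; the source
    material prints only the three frequencies, so the amplitudes, interval
    boundaries, duration and sampling rate are fixed here as documented
    defaults.
    """
    comps = [
        ComponentSpec(freq=10.0, amp=1.0, t_on=0.0, t_off=1.0),
        ComponentSpec(freq=20.0, amp=1.0, t_on=1.0, t_off=2.0),
        ComponentSpec(freq=60.0, amp=1.0, t_on=2.0, t_off=3.0),
    ]
    return composite_signal(comps, fs=500.0, duration=3.0, noise_sd=noise_sd, seed=seed)


THREE_TONE_INTERVALS: tuple[tuple[float, float, float], ...] = (
    (10.0, 0.0, 1.0),
    (20.0, 1.0, 2.0),
    (60.0, 2.0, 3.0),
)
"""(frequency, t_on, t_off) triples of :func:`three_tone_preset`, for checks."""


def eeg_preset(seed: int = 0) -> Signal:
    """Four-channel headband-style surrogate (TP9, AF7, AF8, TP10).

    All channels load equally on the shared source with noise_sd 0.3 at
    256 Hz for 20 s — a generic correlated recording for exercising the
    correlation-matrix stage.
    """
    spec = LatentMixSpec(
        n_channels=4,
        loadings=(1.0, 1.0, 1.0, 1.0),
        noise_sd=0.3,
        fs=256.0,
        duration=20.0,
        seed=seed,
        channel_names=("TP9", "AF7", "AF8", "TP10"),
    )
    return correlated_eeg(spec)


PRESETS = {
    "three-tone": three_tone_preset,
    "eeg": eeg_preset,
}
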