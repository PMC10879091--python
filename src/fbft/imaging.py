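"""Rendering TF maps into classifier-ready images.

A TF map is rendered to a single-channel image (min-max normalised,
optionally log-compressed, frequency increasing upward), the selected
channels' images are composed into one H x W x 3 picture — either mapped
positionally onto the red/green/blue planes (up to 3 channels) or stacked
vertically with a replicated grayscale third dimension (any number) — and
the composite is resized with cubic interpolation to a standard CNN input
geometry (224 x 224, 227 x 227 or 256 x 256).

Every window is normalised on its own min-max so each exported image uses
the full dynamic range; nothing leaks between windows, and reruns are
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import numpy.typing as npt
from PIL import Image

from .baselines import BaselineSpec, baseline_tf
from .fbft_core import TFMap, fbft
from .signal import SegmentSpec, Signal, segment

__all__ = [
    "RenderSpec",
    "CompositeImage",
    "render_tf",
    "compose_channels",
    "export_dataset",
    "CNN_GEOMETRIES",
]

CNN_GEOMETRIES = {
    "googlenet": (224, 224),
    "squeezenet": (227, 227),
    "alexnet": (256, 256),
}
"""Input geometries of the standard pre-trained CNNs (height, width)."""


@dataclass(frozen=True)
class RenderSpec:
    """How to turn magnitudes into pixels.

    ``out_size`` is (height, width); ``colormap`` names a
    perceptually monotone matplotlib colormap applied when a lone channel
    is exported; ``log_scale`` applies ``log(1 + m)`` compression before
    min-max normalisation.  Interpolation is always cubic.
    """

    out_size: tuple[int, int] = (224, 224)
    colormap: str = "viridis"
    log_scale: bool = True

    def __post_init__(self) -> None:
        h, w = self.out_size
        if h < 1 or w < 1:
            raise ValueError(f"out_size must be positive, got {self.out_size}")


@dataclass(frozen=True)
class CompositeImage:
    """H x W x 3 float image in [0, 1] with provenance of its sources."""

    pixels: npt.NDArray[np.float64]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    def to_uint8(self) -> npt.NDArray[np.uint8]:
        return np.round(self.pixels * 255).astype(np.uint8)

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.to_uint8(), mode="RGB").save(path)


def _resize_cubic(img: npt.NDArray[np.float64], out_size: tuple[int, int]) -> npt.NDArray[np.float64]:
    """Cubic resample of a 2-D float image to (height, width)."""
    h, w = out_size
    pil = Image.fromarray(np.ascontiguousarray(img, dtype=np.float32), mode="F")
    out = np.asarray(pil.resize((w, h), resample=Image.BICUBIC), dtype=float)
    return np.clip(out, 0.0, 1.0)  # cubic kernels overshoot at sharp edges


def render_tf(tf: TFMap, spec: RenderSpec | None = None) -> npt.NDArray[np.float64]:
    """Render one TF map as a single-channel image in [0, 1].

    Magnitude is optionally log-compressed (``log(1+m)``), min-max scaled
    over the whole map, flipped so frequency increases upward, and
    resampled to ``spec.out_size`` with cubic interpolation.  An
    all-constant map (min == max) renders as all zeros.
    """
    spec = spec or RenderSpec()
    m = tf.magnitude
    if spec.log_scale:
        m = np.log1p(m)
    lo, hi = m.min(), m.max()
    if hi == lo:
        img = np.zeros_like(m)
    else:
        img = (m - lo) / (hi - lo)
    img = img[::-1]  # row 0 = highest frequency = top of the picture
    if img.shape[0] < 2 or img.shape[1] < 2:
        # a single row/column cannot anchor a cubic kernel; replicate first
        img = np.broadcast_to(img, (max(img.shape[0], 2), max(img.shape[1], 2))).copy()
    return _resize_cubic(img, spec.out_size)


def compose_channels(
    images: list[npt.NDArray[np.float64]],
    mode: str = "rgb",
    channel_names: list[str] | None = None,
) -> CompositeImage:
    """Combine per-channel images into one H x W x 3 composite.

    ``rgb`` maps the first three images positionally onto the red, green
    and blue planes (missing planes zero-filled); it accepts at most 3
    images of equal shape.  ``concat`` stacks any number of images
    vertically in channel order — preserving a common time axis across the
    rows — and replicates the result into all three planes.
    """
    if not images:
        raise ValueError("need at least one image")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images must share one shape, got {sorted(shapes)}")
    names = channel_names or [f"ch{i}" for i in range(len(images))]
    if mode == "rgb":
        if len(images) > 3:
            raise ValueError(
                f"rgb mode takes at most 3 channels, got {len(images)}; "
                "use mode='concat' for more"
            )
        h, w = images[0].shape
        px = np.zeros((h, w, 3))
        for plane, im in enumerate(images):
            px[:, :, plane] = im
        mapping = dict(zip("rgb", names))
    elif mode == "concat":
        stacked = np.vstack(images)
        px = np.repeat(stacked[:, :, np.newaxis], 3, axis=2)
        mapping = {"rows_top_to_bottom": names}
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'rgb' or 'concat'")
    return CompositeImage(
        pixels=np.clip(px, 0.0, 1.0),
        provenance={"mode": mode, "channels": names, "mapping": mapping},
    )


def export_dataset(
    signal: Signal,
    channels: list[str],
    spec: SegmentSpec,
    transform: str = "fbft",
    transform_params: dict[str, Any] | None = None,
    render: RenderSpec | None = None,
    out_dir: str | Path = ".",
    mode: str = "rgb",
    subject: str = "subject",
    label: str | None = None,
) -> dict[str, Any]:
    """Window a recording, transform and render each window, write PNGs.

    One composite image per window is written under ``out_dir`` with the
    deterministic name ``{subject}_{start}s_{transform}.png``; a JSON
    manifest listing every image with its provenance (and the externally
    supplied ``label``) is written as ``manifest.json`` and returned.
    """
    render = render or RenderSpec()
    transform_params = transform_params or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sub = signal.pick(channels)
    windows = segment(sub, spec)
    if not windows:
        warnings.warn("no windows produced; manifest is empty", stacklevel=2)
    entries = []
    for w_idx, win in enumerate(windows):
        per_channel = []
        for name in channels:
            x = win.channel(name)
            if transform == "fbft":
                tf = fbft(x, fs=win.fs, **transform_params)
            else:
                tf = baseline_tf(x, win.fs, BaselineSpec(method=transform, **transform_params))
            per_channel.append(render_tf(tf, render))
        composite = compose_channels(per_channel, mode=mode, channel_names=channels)
        # re-fit the composite to the target geometry (concat changes height)
        if composite.pixels.shape[:2] != render.out_size:
            planes = [
                _resize_cubic(composite.pixels[:, :, p], render.out_size) for p in range(3)
            ]
            composite = CompositeImage(
                pixels=np.clip(np.stack(planes, axis=2), 0.0, 1.0),
                provenance=composite.provenance,
            )
        fname = f"{subject}_{win.t0:08.3f}s_{transform}.png"
        composite.save(out_dir / fname)
        entries.append(
            {
                "file": fname,
                "subject": subject,
                "window_index": w_idx,
                "window_start_s": round(win.t0, 9),
                "window_s": spec.window_s,
                "overlap_s": spec.overlap_s,
                "transform": transform,
                "mode": mode,
                "channels": list(channels),
                "geometry": [int(render.out_size[0]), int(render.out_size[1]), 3],
                "label": label,
            }
        )
    manifest = {
        "subject": subject,
        "n_windows": len(entries),
        "images": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
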