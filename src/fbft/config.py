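"""Validated run configuration for the end-to-end pipeline.

A :class:`RunConfig` captures one batch run — input, channel selection,
windowing, transform, rendering and output — and is validated in full
before any file is touched.  Every run writes its resolved config next to
its outputs so two runs can be compared and reproduced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__


class InputConfig(BaseModel):
    path: str
    format: Optional[Literal["edf", "csv", "wav"]] = None
    fs: Optional[float] = Field(None, gt=0, description="required for csv input")
    delimiter: str = ","


class ChannelConfig(BaseModel):
    """Explicit channel list, or automatic lowest-mCC selection of size k."""

    names: Optional[list[str]] = None
    auto_k: Optional[int] = Field(None, ge=1)

    @model_validator(mode="after")
    def _one_of(self) -> "ChannelConfig":
        if (self.names is None) == (self.auto_k is None):
            raise ValueError("specify exactly one of channels.names or channels.auto_k")
        return self


class WindowConfig(BaseModel):
    window_s: float = Field(gt=0)
    overlap_s: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _overlap_lt_window(self) -> "WindowConfig":
        if self.overlap_s >= self.window_s:
            raise ValueError(
                f"overlap_s ({self.overlap_s}) must be smaller than window_s "
                f"({self.window_s})"
            )
        return self


class TransformConfig(BaseModel):
    method: Literal["fbft", "stft", "cwt", "dwt", "power_spectrum"] = "fbft"
    params: dict[str, Any] = Field(default_factory=dict)


class RenderConfig(BaseModel):
    height: int = Field(224, ge=1)
    width: int = Field(224, ge=1)
    colormap: str = "viridis"
    log_scale: bool = True
    mode: Literal["rgb", "concat"] = "rgb"


class RunConfig(BaseModel):
    input: InputConfig
    channels: ChannelConfig
    window: WindowConfig
    transform: TransformConfig = TransformConfig()
    render: RenderConfig = RenderConfig()
    nan_policy: Literal["drop_samples", "interpolate"] = "drop_samples"
    seed: int = 0
    subject: str = "subject"
    label: Optional[str] = None
    out_dir: str = "fbft_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.model_validate(raw)

    def write_resolved(self, out_dir: str | Path) -> Path:
        """Write the fully resolved config (plus package version) to out_dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {"fbft_version": __version__, **self.model_dump()}
        dest = out / "resolved_config.json"
        with open(dest, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return dest
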