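"""Calibrated image stacks and their on-disk representation.

A :class:`CalibratedStack` is the in-memory container for a multi-channel
time-lapse: a T x C x H x W array scaled to [0, 1] plus channel roles
("BF" brightfield, "EFF" effector dye, "NUC" nuclear dye), frame times in
hours and the pixel size in micrometers.  On disk a stack is a multi-page
TIFF with a YAML sidecar carrying the calibration; OME-TIFF channel metadata
is honored when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = ["CalibratedStack", "read_stack", "write_stack"]


@dataclass
class CalibratedStack:
    """T x C x H x W intensity stack in [0, 1] with calibration metadata."""

    pixels: np.ndarray
    channel_roles: tuple[str, ...]
    times: np.ndarray  # h
    pixel_size: float  # um / pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_roles = tuple(self.channel_roles)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be a T x C x H x W array")
        T, C = self.pixels.shape[:2]
        if len(self.channel_roles) != C:
            raise ValueError(
                f"channel_roles names {len(self.channel_roles)} channels "
                f"but stack has {C}"
            )
        if len(self.times) != T:
            raise ValueError("times length must equal the number of frames")
        if T >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        lo, hi = float(self.pixels.min(initial=0)), float(self.pixels.max(initial=0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError("intensities must lie within [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2:]

    def channel(self, role: str) -> np.ndarray:
        """All frames of one channel role as a T x H x W view."""
        try:
            ci = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not in stack (has {self.channel_roles})"
            ) from None
        return self.pixels[:, ci]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: CalibratedStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.pixels.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "TCYX"},
    )
    side = {
        "pixel_size_um": float(stack.pixel_size),
        "channel_roles": list(stack.channel_roles),
        "times_h": [float(t) for t in stack.times],
        "metadata": {k: _plain(v) for k, v in stack.metadata.items()},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(side, sort_keys=True))
    return path


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_stack(
    path: str | Path, channel_map: Sequence[str] | None = None
) -> CalibratedStack:
    """Read a TIFF stack with its YAML sidecar (or OME metadata).

    ``channel_map`` names the channel roles in order; when omitted the sidecar
    roles are used.  Integer pixel data are rescaled to [0, 1] by the dtype
    full scale.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing calibration sidecar {sidecar.name}: need pixel_size_um and times_h"
        )
    side = yaml.safe_load(sidecar.read_text())
    for key in ("pixel_size_um", "times_h", "channel_roles"):
        if key not in side:
            raise ValueError(f"calibration sidecar missing required field {key!r}")

    roles = tuple(channel_map) if channel_map is not None else tuple(side["channel_roles"])
    if pixels.ndim == 3:  # single channel stored as T x H x W
        pixels = pixels[:, None]
    if pixels.ndim != 4:
        raise ValueError(f"expected a T x C x H x W TIFF, got shape {pixels.shape}")
    if pixels.shape[1] != len(roles):
        raise ValueError(
            f"stack has {pixels.shape[1]} channels but channel map names {len(roles)}"
        )
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float64) / np.iinfo(pixels.dtype).max
    else:
        pixels = pixels.astype(np.float64)

    return CalibratedStack(
        pixels=pixels,
        channel_roles=roles,
        times=np.asarray(side["times_h"], dtype=float),
        pixel_size=float(side["pixel_size_um"]),
        metadata=dict(side.get("metadata") or {}),
    )
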