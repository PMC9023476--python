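"""Calibrated grayscale image stacks.

A :class:`FrameStack` is the in-memory form of one conjunctival video: a
time-ordered ``(T, H, W)`` intensity array together with the physical
calibration (frames per second, micrometres per pixel) every downstream
measurement depends on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["FrameStack"]


@dataclass
class FrameStack:
    """A time-ordered grayscale video with physical calibration.

    Parameters
    ----------
    frames
        ``(T, H, W)`` float array of intensities.
    fps
        Acquisition rate in frames per second (> 0).
    um_per_px
        Spatial calibration in micrometres per pixel (> 0).
    """

    frames: np.ndarray
    fps: float = 60.0
    um_per_px: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if not self.um_per_px > 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def dt_s(self) -> float:
        """Inter-frame interval in seconds."""
        return 1.0 / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def copy_with(self, frames: np.ndarray) -> "FrameStack":
        return FrameStack(frames=frames, fps=self.fps, um_per_px=self.um_per_px,
                          meta=dict(self.meta))

    # ------------------------------------------------------------------ IO
    def to_tiff(self, path: str | Path) -> Path:
        """Write as a multi-page TIFF plus a calibration sidecar JSON."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"fps": self.fps, "um_per_px": self.um_per_px, **self.meta}))
        return path

    @classmethod
    def from_tiff(cls, path: str | Path, fps: float | None = None,
                  um_per_px: float | None = None) -> "FrameStack":
        """Read a multi-page TIFF; calibration from sidecar JSON if present."""
        path = Path(path)
        frames = tifffile.imread(path)
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        fps = fps if fps is not None else meta.pop("fps", 60.0)
        um_per_px = (um_per_px if um_per_px is not None
                     else meta.pop("um_per_px", 1.0))
        return cls(frames=frames, fps=fps, um_per_px=um_per_px, meta=meta)

    @classmethod
    def from_pngs(cls, paths: Sequence[str | Path], fps: float = 60.0,
                  um_per_px: float = 1.0) -> "FrameStack":
        """Read an ordered sequence of numbered PNG frames."""
        if not paths:
            raise ValueError("no frame paths given")
        frames = np.stack([np.asarray(iio.imread(p), dtype=np.float64)
                           for p in paths])
        if frames.ndim == 4:  # RGB(A) -> luminance
            frames = frames[..., :3].mean(axis=-1)
        return cls(frames=frames, fps=fps, um_per_px=um_per_px)
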