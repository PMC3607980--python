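"""Reading video files into frame stacks, grayscale conversion, cropping."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import _avi
from .errors import ConfigurationError, ValidationError, VideoReadError

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights, offered as an alternative to the channel mean.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of grayscale frames with its recording rate.

    Attributes
    ----------
    frames
        ``(n_frames, height, width)`` array of non-negative intensities.
    frame_rate
        Recording rate in frames per second (> 0).
    source_path
        Provenance string (file path or synthetic tag).
    """

    frames: np.ndarray
    frame_rate: float
    source_path: str = field(default="<memory>")

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValidationError(f"frames must be 3-D (frame, row, col); got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValidationError(f"a frame stack needs at least 2 frames; got {frames.shape[0]}")
        if frames.shape[1] < 1 or frames.shape[2] < 1:
            raise ValidationError("frame height and width must be at least 1 pixel")
        if not np.all(np.isfinite(frames)):
            raise ValidationError("frame intensities must be finite")
        if frames.min() < 0:
            raise ValidationError("frame intensities must be non-negative")
        if not (self.frame_rate > 0):
            raise ValidationError(f"frame_rate must be > 0; got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


def to_grayscale(frames: np.ndarray, *, method: str = "mean") -> np.ndarray:
    """Collapse an ``(n, h, w, 3)`` RGB stack to ``(n, h, w)`` grayscale.

    ``method="mean"`` averages the channels; ``method="luma"`` applies
    BT.601 weights. Already-grayscale input is returned unchanged.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        rgb = frames[..., :3].astype(np.float64)
        if method == "mean":
            return rgb.mean(axis=-1)
        if method == "luma":
            return rgb @ np.asarray(LUMA_WEIGHTS)
        raise ValidationError(f"unknown grayscale method {method!r}")
    raise ValidationError(f"cannot interpret frame array of shape {frames.shape}")


def _read_tiff(path: Path):
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        fps = None
        meta = tif.imagej_metadata
        if meta:
            if meta.get("fps"):
                fps = float(meta["fps"])
            elif meta.get("finterval"):
                fps = 1.0 / float(meta["finterval"])
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    return frames, fps


def read_video(path, frame_rate_override: float | None = None, *,
               grayscale: str = "mean") -> FrameStack:
    """Read an AVI or multi-page TIFF file into a :class:`FrameStack`.

    RGB input is converted to grayscale. An explicit
    ``frame_rate_override`` always wins over container metadata (camera
    metadata is frequently wrong); without metadata it is required.
    """
    path = Path(path)
    if not path.exists():
        raise VideoReadError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            frames, meta_fps = _read_tiff(path)
        elif suffix == ".avi":
            frames, meta_fps = _avi.read_avi(path)
        else:
            raise VideoReadError(f"unsupported video format {suffix!r} for {path}")
    except VideoReadError:
        raise
    except Exception as exc:  # corrupt container / decoder failure
        raise VideoReadError(f"cannot decode {path}: {exc}") from exc

    if frame_rate_override is not None:
        if not (frame_rate_override > 0):
            raise ValidationError(f"frame rate override must be > 0; got {frame_rate_override}")
        if meta_fps is not None and abs(meta_fps - frame_rate_override) > 1e-6:
            logger.warning("%s: overriding metadata frame rate %.6g with %.6g",
                           path, meta_fps, frame_rate_override)
        fps = float(frame_rate_override)
    elif meta_fps is not None:
        fps = float(meta_fps)
    else:
        raise ConfigurationError(
            f"{path} carries no frame rate metadata; pass frame_rate_override (--fps)")

    frames = to_grayscale(frames, method=grayscale)
    if frames.shape[0] < 2:
        raise ValidationError(f"{path}: at least 2 frames are required, got {frames.shape[0]}")
    return FrameStack(frames=frames.astype(np.float64), frame_rate=fps,
                      source_path=str(path))


def crop(stack: FrameStack, region: tuple[int, int, int, int]) -> FrameStack:
    """Spatially crop every frame to ``region = (x, y, width, height)``.

    The frame count and frame rate are untouched, so the achievable
    frequency resolution is unchanged — cropping only speeds things up.
    """
    x, y, w, h = (int(v) for v in region)
    if w < 1 or h < 1:
        raise ValidationError(f"crop region must be at least 1x1 px; got {w}x{h}")
    if x < 0 or y < 0 or x + w > stack.width or y + h > stack.height:
        raise ValidationError(
            f"crop region {region} outside frame bounds {stack.width}x{stack.height}")
    return FrameStack(frames=stack.frames[:, y : y + h, x : x + w],
                      frame_rate=stack.frame_rate, source_path=stack.source_path)
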