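"""Ground-truth synthetic videos of oscillating regions.

Emulates the light-intensity fluctuations around beating cilia: each
rectangular region oscillates at a known frequency (sine, sawtooth or
square waveform) on top of a baseline, with optional per-pixel Gaussian
noise and an optional global flicker term mimicking an unstable lamp.
Every other module can therefore be validated against exact ground
truth without any real recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import signal as sp_signal

from . import _avi
from .errors import ValidationError
from .video_io import FrameStack

WAVEFORMS = ("sine", "sawtooth", "square")


@dataclass(frozen=True)
class RegionSpec:
    """One oscillating rectangle: ``rect = (x, y, width, height)`` px."""

    rect: tuple[int, int, int, int]
    frequency: float            # Hz
    amplitude: float            # intensity units
    waveform: str = "sine"
    phase: float = 0.0          # radians
    baseline: float = 0.0       # added inside the region only

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORMS:
            raise ValidationError(f"waveform must be one of {WAVEFORMS}; got {self.waveform!r}")
        if self.frequency <= 0:
            raise ValidationError(f"region frequency must be > 0; got {self.frequency}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a deterministic synthetic recording."""

    frame_rate: float
    n_frames: int
    height: int
    width: int
    regions: tuple[RegionSpec, ...] = ()
    noise_sd: float = 0.0
    baseline: float = 0.0                          # global background level
    flicker: tuple[float, float] | None = None     # (frequency Hz, amplitude)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.frame_rate <= 0 or self.n_frames < 2:
            raise ValidationError("need frame_rate > 0 and n_frames >= 2")
        if self.height < 1 or self.width < 1:
            raise ValidationError("frame size must be at least 1x1 px")
        nyquist = self.frame_rate / 2
        for reg in self.regions:
            if reg.frequency >= nyquist:
                raise ValidationError(
                    f"region frequency {reg.frequency} Hz violates the Nyquist limit "
                    f"{nyquist} Hz at {self.frame_rate} fps")
            x, y, w, h = reg.rect
            if x < 0 or y < 0 or w < 1 or h < 1 or x + w > self.width or y + h > self.height:
                raise ValidationError(f"region {reg.rect} outside {self.width}x{self.height} frame")
        if self.flicker is not None and self.flicker[0] >= nyquist:
            raise ValidationError("flicker frequency violates the Nyquist limit")


def _waveform(kind: str, angle: np.ndarray) -> np.ndarray:
    if kind == "sine":
        return np.sin(angle)
    if kind == "sawtooth":
        return sp_signal.sawtooth(angle)
    return sp_signal.square(angle)


def generate_video(spec: SyntheticSpec) -> tuple[FrameStack, np.ndarray]:
    """Render the spec into a float frame stack plus a truth map.

    Returns ``(stack, truth)`` where ``truth[y, x]`` is the ground-truth
    oscillation frequency at each pixel (0 where nothing oscillates).
    Identical specs (same seed) produce identical output. The float
    stack is shifted, if needed, so intensities stay non-negative; the
    shift is constant and invisible to DC-removed spectra.
    """
    t = np.arange(spec.n_frames) / spec.frame_rate
    frames = np.full((spec.n_frames, spec.height, spec.width), float(spec.baseline))
    truth = np.zeros((spec.height, spec.width))

    for reg in spec.regions:
        x, y, w, h = reg.rect
        trace = reg.baseline + reg.amplitude * _waveform(
            reg.waveform, 2 * np.pi * reg.frequency * t + reg.phase)
        frames[:, y : y + h, x : x + w] += trace[:, None, None]
        truth[y : y + h, x : x + w] = reg.frequency

    if spec.flicker is not None:
        f_flick, a_flick = spec.flicker
        frames += (a_flick * np.sin(2 * np.pi * f_flick * t))[:, None, None]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)

    low = frames.min()
    if low < 0:
        frames -= low  # uniform shift; keeps FrameStack's non-negativity invariant
    stack = FrameStack(frames=frames, frame_rate=spec.frame_rate,
                       source_path=f"<synthetic seed={spec.seed}>")
    return stack, truth


def write_synthetic_video(stack: FrameStack, path, format: str | None = None) -> Path:
    """Write a stack losslessly as 8-bit AVI or TIFF.

    Intensities are rounded and clipped to 0..255. The frame rate is
    stored in the container (AVI stream header / ImageJ TIFF metadata)
    so :func:`~ciliafreq.video_io.read_video` round-trips without an
    override.
    """
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "avi"
    quantized = np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8)
    if format == "avi":
        _avi.write_avi(path, quantized, stack.frame_rate)
    elif format == "tiff":
        tifffile.imwrite(path, quantized, imagej=True,
                         metadata={"fps": float(stack.frame_rate), "axes": "TYX"})
    else:
        raise ValidationError(f"unknown format {format!r}; use 'avi' or 'tiff'")
    return path


def truth_to_csv(truth: np.ndarray, path) -> None:
    """Write the per-pixel truth map as ``y,x,frequency_hz`` rows (nonzero only)."""
    with open(path, "w", newline="") as fh:
        fh.write("y,x,frequency_hz\n")
        ys, xs = np.nonzero(truth)
        for y, x in zip(ys.tolist(), xs.tolist()):
            fh.write(f"{y},{x},{float(truth[y, x])!r}\n")


def spec_from_yaml(path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML file.

    Schema::

        frame_rate: 250.0
        n_frames: 512
        height: 120
        width: 120
        baseline: 100.0
        noise_sd: 1.0
        seed: 42
        flicker: {frequency: 50.0, amplitude: 2.0}   # optional
        regions:
          - rect: [10, 10, 40, 40]      # x, y, width, height
            frequency: 12.0
            amplitude: 30.0
            waveform: sine              # sine | sawtooth | square
            phase: 0.0
            baseline: 0.0
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: YAML spec must be a mapping")
    regions = tuple(
        RegionSpec(rect=tuple(r["rect"]), frequency=float(r["frequency"]),
                   amplitude=float(r["amplitude"]), waveform=r.get("waveform", "sine"),
                   phase=float(r.get("phase", 0.0)), baseline=float(r.get("baseline", 0.0)))
        for r in data.get("regions", []))
    flicker = None
    if data.get("flicker"):
        flicker = (float(data["flicker"]["frequency"]), float(data["flicker"]["amplitude"]))
    return SyntheticSpec(
        frame_rate=float(data["frame_rate"]), n_frames=int(data["n_frames"]),
        height=int(data["height"]), width=int(data["width"]), regions=regions,
        noise_sd=float(data.get("noise_sd", 0.0)), baseline=float(data.get("baseline", 0.0)),
        flicker=flicker, seed=int(data.get("seed", 0)))
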