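"""Minimal uncompressed AVI (RIFF) container support.

Only the subset of the format needed for lossless high-speed microscopy
clips is implemented: a single ``vids`` stream with raw DIB frames,
either 8-bit palettized grayscale or 24-bit BGR, bottom-up rows padded
to 4-byte boundaries. No third-party decoder is required, which keeps
intensity values bit-exact.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import VideoReadError

_AVIH = struct.Struct("<14I")
_STRH = struct.Struct("<4s4sI2H8I4h")
_BMIH = struct.Struct("<I2i2H2I2i2I")

# dwFlags: AVIF_HASINDEX | AVIF_WASCAPTUREFILE not needed; keep 0.
_FPS_SCALE = 1_000_000  # store fps as rate/scale rational with µs precision


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def _gray_palette() -> bytes:
    # RGBQUAD (B, G, R, reserved) identity grayscale ramp
    return b"".join(struct.pack("<4B", i, i, i, 0) for i in range(256))


def write_avi(path, frames: np.ndarray, frame_rate: float, *, pixel_format: str = "gray8") -> None:
    """Write ``frames`` to an uncompressed AVI file.

    Parameters
    ----------
    frames
        ``(n, h, w)`` uint8 array for ``gray8``; ``(n, h, w, 3)`` uint8
        RGB array for ``rgb24``.
    frame_rate
        Frames per second, stored as a rate/scale rational.
    pixel_format
        ``"gray8"`` (palettized DIB) or ``"rgb24"``.
    """
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        raise ValueError("AVI writer requires uint8 frames")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if pixel_format == "gray8":
        if frames.ndim != 3:
            raise ValueError("gray8 expects (n, h, w) frames")
        bit_count, palette = 8, _gray_palette()
    elif pixel_format == "rgb24":
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ValueError("rgb24 expects (n, h, w, 3) frames")
        bit_count, palette = 24, b""
    else:
        raise ValueError(f"unknown pixel_format {pixel_format!r}")

    n, h, w = frames.shape[:3]
    row_bytes = (w * bit_count // 8 + 3) & ~3
    frame_bytes = row_bytes * h

    def encode(frame: np.ndarray) -> bytes:
        if bit_count == 8:
            rows = frame[::-1]  # bottom-up
        else:
            rows = frame[::-1, :, ::-1].reshape(h, -1)  # bottom-up, RGB->BGR
        padded = np.zeros((h, row_bytes), dtype=np.uint8)
        padded[:, : rows.shape[1]] = rows
        return padded.tobytes()

    rate = round(frame_rate * _FPS_SCALE)
    avih = _chunk(
        b"avih",
        _AVIH.pack(
            round(1e6 / frame_rate),  # dwMicroSecPerFrame
            frame_bytes * round(frame_rate + 1),
            0, 0, n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
        ),
    )
    strh = _chunk(
        b"strh",
        _STRH.pack(
            b"vids", b"DIB ", 0, 0, 0, 0,
            _FPS_SCALE, rate,  # dwScale, dwRate -> fps = rate/scale
            0, n, frame_bytes, 0, 0, 0, 0, w, h,
        ),
    )
    strf = _chunk(
        b"strf",
        _BMIH.pack(40, w, h, 1, bit_count, 0, frame_bytes, 0, 0,
                   256 if bit_count == 8 else 0, 0) + palette,
    )
    hdrl = _list(b"hdrl", avih + _list(b"strl", strh + strf))
    movi = _list(b"movi", b"".join(_chunk(b"00db", encode(f)) for f in frames))
    riff = _chunk(b"RIFF", b"AVI " + hdrl + movi)
    Path(path).write_bytes(riff)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path):
    """Read an uncompressed AVI file.

    Returns
    -------
    frames : np.ndarray
        ``(n, h, w)`` uint8 for grayscale input, ``(n, h, w, 3)`` uint8
        RGB for 24-bit input.
    frame_rate : float or None
        Frames per second from the stream header, if present.
    """
    path = Path(path)
    try:
        buf = path.read_bytes()
    except OSError as exc:
        raise VideoReadError(f"cannot read {path}: {exc}") from exc
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise VideoReadError(f"{path} is not an AVI file")

    width = height = bit_count = None
    compression = 0
    palette = None
    rate = scale = None
    usec_per_frame = None
    frame_payloads: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bit_count, compression, palette, rate, scale, usec_per_frame
        for fourcc, off, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(off + 4, off + size)
            elif fourcc == b"avih" and size >= _AVIH.size:
                usec_per_frame = struct.unpack_from("<I", buf, off)[0]
            elif fourcc == b"strh" and size >= 32:
                if buf[off : off + 4] == b"vids":
                    scale, rate = struct.unpack_from("<2I", buf, off + 20)
            elif fourcc == b"strf" and size >= _BMIH.size and width is None:
                (_, width, height, _, bit_count, compression, *_rest) = _BMIH.unpack_from(buf, off)
                if bit_count == 8:
                    pal = buf[off + _BMIH.size : off + size]
                    palette = np.frombuffer(pal, dtype=np.uint8).reshape(-1, 4)[:, :3][:, ::-1]
            elif fourcc in (b"00db", b"00dc"):
                frame_payloads.append(buf[off : off + size])

    walk(12, len(buf))

    if width is None or bit_count is None:
        raise VideoReadError(f"{path}: no video stream format found")
    if compression != 0:
        raise VideoReadError(f"{path}: compressed AVI streams are not supported")
    if bit_count not in (8, 24):
        raise VideoReadError(f"{path}: unsupported bit depth {bit_count}")
    if not frame_payloads:
        raise VideoReadError(f"{path}: no frames found")

    h = abs(height)
    top_down = height < 0
    row_bytes = (width * bit_count // 8 + 3) & ~3
    frames = []
    for payload in frame_payloads:
        if len(payload) < row_bytes * h:
            raise VideoReadError(f"{path}: truncated frame data")
        arr = np.frombuffer(payload[: row_bytes * h], dtype=np.uint8).reshape(h, row_bytes)
        if bit_count == 8:
            frame = arr[:, :width]
        else:
            frame = arr[:, : width * 3].reshape(h, width, 3)[:, :, ::-1]  # BGR->RGB
        if not top_down:
            frame = frame[::-1]
        frames.append(frame)
    stack = np.ascontiguousarray(np.stack(frames))

    if bit_count == 8 and palette is not None and len(palette) >= 256:
        ramp = np.arange(256, dtype=np.uint8)
        if not (np.array_equal(palette[:256, 0], ramp)
                and np.array_equal(palette[:256, 1], ramp)
                and np.array_equal(palette[:256, 2], ramp)):
            stack = palette[:256][stack]  # non-grayscale palette -> RGB

    fps = None
    if rate and scale:
        fps = rate / scale
    elif usec_per_frame:
        fps = 1e6 / usec_per_frame
    return stack, fps
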