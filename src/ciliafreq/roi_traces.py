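"""Rectangular ROI grids and per-ROI mean-intensity time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .video_io import FrameStack

MAX_GRID = 40  # at most 40x40 ROIs = 1600 traces per field


@dataclass(frozen=True)
class RoiGrid:
    """A top-left-anchored tiling of equal-sized rectangular ROIs.

    Remainder pixels that do not fill a whole ROI at the right/bottom
    edges are excluded, keeping every ROI the same size so spectra are
    comparable across the grid. ROIs are ordered row-major.
    """

    n_rows: int
    n_cols: int
    roi_height_px: int
    roi_width_px: int
    origin: tuple[int, int] = (0, 0)  # (y, x) of the grid's top-left pixel

    def __post_init__(self) -> None:
        if not (1 <= self.n_rows <= MAX_GRID and 1 <= self.n_cols <= MAX_GRID):
            raise ValidationError(
                f"grid must be between 1x1 and {MAX_GRID}x{MAX_GRID}; "
                f"got {self.n_rows}x{self.n_cols}")
        if self.roi_height_px < 1 or self.roi_width_px < 1:
            raise ValidationError("each ROI must be at least 1x1 px")

    @property
    def n_rois(self) -> int:
        return self.n_rows * self.n_cols

    def roi_bounds(self, index: int) -> tuple[int, int, int, int]:
        """(y0, x0, y1, x1) pixel bounds of ROI ``index`` (row-major)."""
        r, c = divmod(index, self.n_cols)
        y0 = self.origin[0] + r * self.roi_height_px
        x0 = self.origin[1] + c * self.roi_width_px
        return y0, x0, y0 + self.roi_height_px, x0 + self.roi_width_px


@dataclass(frozen=True)
class IntensityTraces:
    """Per-ROI mean-intensity time series: ``values[roi, frame]``."""

    values: np.ndarray
    grid: RoiGrid
    frame_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("trace matrix must be 2-D (ROI, frame)")
        if values.shape[0] != self.grid.n_rois:
            raise ValidationError(
                f"trace count {values.shape[0]} != grid ROI count {self.grid.n_rois}")
        if not (self.frame_rate > 0):
            raise ValidationError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def make_grid(frame_height: int, frame_width: int, n_rows: int, n_cols: int) -> RoiGrid:
    """Build an ``n_rows`` x ``n_cols`` grid for a frame of the given size.

    ROI size is the integer division of the frame size by the grid
    shape; leftover edge pixels are excluded.
    """
    if not (1 <= n_rows <= MAX_GRID and 1 <= n_cols <= MAX_GRID):
        raise ValidationError(
            f"grid must be between 1x1 and {MAX_GRID}x{MAX_GRID}; got {n_rows}x{n_cols}")
    roi_h = frame_height // n_rows
    roi_w = frame_width // n_cols
    if roi_h < 1 or roi_w < 1:
        raise ValidationError(
            f"a {n_rows}x{n_cols} grid does not fit a {frame_height}x{frame_width} frame "
            "(each ROI must be at least 1 px)")
    return RoiGrid(n_rows=n_rows, n_cols=n_cols, roi_height_px=roi_h, roi_width_px=roi_w)


def default_grid(frame_height: int, frame_width: int) -> RoiGrid:
    """Largest feasible grid up to 40x40 for the given frame size."""
    return make_grid(frame_height, frame_width,
                     min(MAX_GRID, frame_height), min(MAX_GRID, frame_width))


def extract_traces(stack: FrameStack, grid: RoiGrid) -> IntensityTraces:
    """Average pixel intensity inside each ROI on every frame.

    ``values[r, t]`` is the arithmetic mean over ROI ``r``'s pixels on
    frame ``t``.
    """
    y0, x0 = grid.origin
    h_cov = grid.n_rows * grid.roi_height_px
    w_cov = grid.n_cols * grid.roi_width_px
    if y0 < 0 or x0 < 0 or y0 + h_cov > stack.height or x0 + w_cov > stack.width:
        raise ValidationError(
            f"grid ({grid.n_rows}x{grid.n_cols} ROIs of "
            f"{grid.roi_height_px}x{grid.roi_width_px} px at {grid.origin}) "
            f"does not fit a {stack.height}x{stack.width} frame")
    covered = stack.frames[:, y0 : y0 + h_cov, x0 : x0 + w_cov]
    # (t, R, rh, C, cw) -> mean over (rh, cw), then flatten (R, C) row-major
    blocks = covered.reshape(stack.n_frames, grid.n_rows, grid.roi_height_px,
                             grid.n_cols, grid.roi_width_px)
    means = blocks.mean(axis=(2, 4)).reshape(stack.n_frames, grid.n_rois)
    return IntensityTraces(values=means.T.copy(), grid=grid, frame_rate=stack.frame_rate)


def traces_to_csv(traces: IntensityTraces, path) -> None:
    """Export raw traces: one row per ROI, 1-based (row, col) labels."""
    grid = traces.grid
    with open(path, "w", newline="") as fh:
        header = ["roi_row", "roi_col"] + [f"I_t{t}" for t in range(traces.n_frames)]
        fh.write(",".join(header) + "\n")
        for i in range(grid.n_rois):
            r, c = divmod(i, grid.n_cols)
            vals = ",".join(repr(float(v)) for v in traces.values[i])
            fh.write(f"{r + 1},{c + 1},{vals}\n")
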