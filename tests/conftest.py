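import numpy as np
import pytest

from ciliafreq.roi_traces import RoiGrid, IntensityTraces
from ciliafreq.synthetic import RegionSpec, SyntheticSpec
from ciliafreq.video_io import FrameStack


def brute_force_dft_mag(trace):
    """Independent O(N^2) DFT magnitude oracle (DC-removed), k = 0..N//2."""
    x = np.asarray(trace, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    ns = np.arange(n)
    return np.array([
        abs(np.sum(x * np.exp(-2j * np.pi * k * ns / n))) for k in range(n // 2 + 1)
    ])


@pytest.fixture
def single_trace():
    """Factory wrapping a 1-D trace as a 1x1-ROI IntensityTraces."""

    def make(values, frame_rate=250.0):
        values = np.asarray(values, dtype=np.float64)
        grid = RoiGrid(n_rows=1, n_cols=1, roi_height_px=1, roi_width_px=1)
        return IntensityTraces(values=values[None, :], grid=grid, frame_rate=frame_rate)

    return make


@pytest.fixture
def sine_stack():
    """Factory for a half-oscillating / half-static synthetic stack."""

    def make(frequency=12.0, frame_rate=250.0, n_frames=512, size=80,
             amplitude=40.0, noise_sd=0.0, seed=0):
        spec = SyntheticSpec(
            frame_rate=frame_rate, n_frames=n_frames, height=size, width=size,
            regions=(RegionSpec(rect=(0, 0, size // 2, size), frequency=frequency,
                                amplitude=amplitude, baseline=120.0),),
            baseline=60.0, noise_sd=noise_sd, seed=seed)
        from ciliafreq.synthetic import generate_video

        return generate_video(spec)

    return make


@pytest.fixture
def constant_stack():
    def make(value=7.0, n_frames=16, height=20, width=20, frame_rate=100.0):
        return FrameStack(frames=np.full((n_frames, height, width), float(value)),
                          frame_rate=frame_rate)

    return make
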