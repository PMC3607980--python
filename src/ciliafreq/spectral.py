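"""FFT magnitude spectra, dominant-frequency estimation and noise rejection.

Each ROI trace is mean-subtracted, transformed, and reduced to a single
beat frequency. The dominant in-band peak must beat the low-frequency
background by a signal-to-noise factor (default 3x) and fall inside a
physiologically plausible band, otherwise the ROI is reported as 0 Hz
with a rejection reason. An accepted peak is refined to sub-bin
precision by a magnitude-weighted average over the peak and its two
flanking bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .roi_traces import IntensityTraces, RoiGrid

#: Band presets in Hz: airway cilia beat ~3-20 Hz, brain ependymal up to 60 Hz.
BAND_PRESETS = {"respiratory": (3.0, 20.0), "ependymal": (3.0, 60.0)}

#: Spectral bins treated as low-frequency background (DC bin excluded).
BACKGROUND_BINS = (1, 2, 3)

DEFAULT_SNR_FACTOR = 3.0
#: Below this magnitude the whole (DC-removed) spectrum counts as static.
STATIC_TOL = 1e-8

REASON_NONE = "none"
REASON_STATIC = "static"
REASON_BELOW_SNR = "below_snr"
REASON_OUT_OF_BAND = "out_of_band"


@dataclass(frozen=True)
class BandFilter:
    """A frequency acceptance band ``[f_min, f_max]`` in Hz."""

    f_min: float
    f_max: float
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValidationError(
                f"band requires 0 < f_min < f_max; got [{self.f_min}, {self.f_max}]")

    @classmethod
    def from_preset(cls, name: str) -> "BandFilter":
        try:
            lo, hi = BAND_PRESETS[name]
        except KeyError:
            raise ValidationError(
                f"unknown band preset {name!r}; choose from {sorted(BAND_PRESETS)}") from None
        return cls(lo, hi, preset=name)

    def contains(self, freq: float) -> bool:
        return self.f_min <= freq <= self.f_max


@dataclass(frozen=True)
class SpectrumSet:
    """Magnitude spectra per ROI: ``magnitudes[roi, k]`` for k = 0..n_fft//2."""

    magnitudes: np.ndarray
    fr: float          # frequency resolution, Hz per bin
    n_fft: int
    frame_rate: float
    grid: RoiGrid | None = field(default=None)

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.magnitudes.shape[1]) * self.fr


@dataclass(frozen=True)
class CbfMap:
    """Per-ROI beat frequency; 0 Hz encodes a rejected or static ROI."""

    cbf: np.ndarray               # (n_rows, n_cols) Hz
    rejection_reason: np.ndarray  # (n_rows, n_cols) reason strings
    grid: RoiGrid
    fr: float
    band: BandFilter

    def __post_init__(self) -> None:
        if self.cbf.shape != self.rejection_reason.shape:
            raise ValidationError("cbf and rejection_reason shapes differ")
        rejected = self.rejection_reason != REASON_NONE
        if np.any((self.cbf == 0) != rejected):
            raise ValidationError("cbf must be 0 exactly for rejected ROIs")

    @property
    def accepted(self) -> np.ndarray:
        """Boolean mask of ROIs with a measured (nonzero) frequency."""
        return self.rejection_reason == REASON_NONE


def frequency_resolution(frame_rate: float, n_frames: int) -> float:
    """Spectral bin spacing in Hz: recording frame rate / frame count."""
    if not (frame_rate > 0):
        raise ValidationError(f"frame_rate must be > 0; got {frame_rate}")
    if n_frames < 2:
        raise ValidationError(f"n_frames must be >= 2; got {n_frames}")
    return frame_rate / n_frames


def _resolve_n_fft(n_frames: int, policy: str) -> int:
    if policy == "pow2":
        return 1 << (n_frames.bit_length() - 1)
    if policy == "full":
        return n_frames
    raise ValidationError(f"unknown n_fft policy {policy!r}; use 'pow2' or 'full'")


def compute_spectrum(traces: IntensityTraces, n_fft_policy: str = "pow2", *,
                     window: str = "rect") -> SpectrumSet:
    """Magnitude spectrum of each DC-removed trace.

    The trace mean is subtracted, the trace is truncated to ``n_fft``
    frames (largest power of two <= length under the default ``pow2``
    policy), and ``|X_k|`` is stored for k = 0..n_fft//2. No window is
    applied by default; ``window="hann"`` trades leakage for peak width.
    """
    if traces.n_frames < 4:
        raise ValidationError(f"traces must have at least 4 frames; got {traces.n_frames}")
    n_fft = _resolve_n_fft(traces.n_frames, n_fft_policy)
    segment = traces.values[:, :n_fft]
    segment = segment - segment.mean(axis=1, keepdims=True)
    if window == "hann":
        segment = segment * np.hanning(n_fft)
    elif window != "rect":
        raise ValidationError(f"unknown window {window!r}")
    mags = np.abs(np.fft.rfft(segment, axis=1))
    return SpectrumSet(magnitudes=mags, fr=traces.frame_rate / n_fft, n_fft=n_fft,
                       frame_rate=traces.frame_rate, grid=traces.grid)


def band_bins(band: BandFilter, fr: float, n_bins: int) -> tuple[int, int]:
    """Inclusive bin-index range covered by ``band`` (DC bin excluded)."""
    k_lo = max(1, math.ceil(band.f_min / fr - 1e-12))
    k_hi = min(n_bins - 1, math.floor(band.f_max / fr + 1e-12))
    if k_lo > k_hi:
        raise ValidationError(
            f"band [{band.f_min}, {band.f_max}] Hz maps to no spectral bin at fr={fr:.6g}")
    return k_lo, k_hi


def dominant_peak(magnitudes: np.ndarray, band: BandFilter, fr: float) -> tuple[int, float]:
    """Bin of maximal magnitude whose frequency lies in ``band``.

    Ties break toward the lower bin. Returns ``(peak_bin, peak_mag)``.
    """
    magnitudes = np.asarray(magnitudes)
    k_lo, k_hi = band_bins(band, fr, magnitudes.shape[0])
    window = magnitudes[k_lo : k_hi + 1]
    k = k_lo + int(np.argmax(window))
    return k, float(magnitudes[k])


def flanking_average(magnitudes: np.ndarray, peak_bin: int, fr: float, *,
                     mode: str = "centroid") -> float:
    """Sub-bin frequency estimate around ``peak_bin``.

    ``centroid`` (default): magnitude-weighted mean frequency over the
    peak and its two flanking bins; symmetric flanks leave the estimate
    on the peak. ``mean3``: unweighted mean of the three bin
    frequencies. ``raw``: the peak bin frequency itself. A missing
    flank at the spectrum edge contributes zero magnitude.
    """
    magnitudes = np.asarray(magnitudes, dtype=np.float64)
    n = magnitudes.shape[0]
    if not (0 <= peak_bin < n):
        raise ValidationError(f"peak_bin {peak_bin} outside spectrum of {n} bins")
    if mode == "raw":
        return peak_bin * fr
    ks = np.arange(peak_bin - 1, peak_bin + 2)
    valid = (ks >= 0) & (ks < n)
    mags = np.where(valid, magnitudes[ks.clip(0, n - 1)], 0.0)
    if mode == "mean3":
        return float(ks[valid].mean()) * fr
    if mode == "centroid":
        total = mags.sum()
        if total == 0:
            return peak_bin * fr
        return float((ks * fr * mags).sum() / total)
    raise ValidationError(f"unknown peak mode {mode!r}")


def noise_reject(magnitudes: np.ndarray, peak_bin: int, peak_freq: float,
                 band: BandFilter, snr_factor: float = DEFAULT_SNR_FACTOR, *,
                 static_tol: float = STATIC_TOL) -> str:
    """Classify a spectrum's peak against the acceptance rules.

    Background is the maximum magnitude of the first three non-DC bins.
    Returns a rejection reason, or ``"none"`` if the peak is accepted.
    """
    magnitudes = np.asarray(magnitudes, dtype=np.float64)
    if magnitudes[1:].max(initial=0.0) <= static_tol:
        return REASON_STATIC
    background = magnitudes[list(BACKGROUND_BINS)].max()
    if magnitudes[peak_bin] <= snr_factor * background:
        return REASON_BELOW_SNR
    if not band.contains(peak_freq):
        return REASON_OUT_OF_BAND
    return REASON_NONE


def compute_cbf(traces: IntensityTraces, band: BandFilter, *,
                snr_factor: float = DEFAULT_SNR_FACTOR, n_fft_policy: str = "pow2",
                peak_mode: str = "centroid", window: str = "rect",
                static_tol: float = STATIC_TOL) -> CbfMap:
    """Full per-ROI pipeline: spectrum -> peak -> rejection -> refinement.

    The dominant peak is searched over the whole non-DC spectrum up to
    Nyquist, so genuinely out-of-band oscillations (drift, flicker) are
    rejected rather than mapped onto the nearest in-band bin.
    """
    spectra = compute_spectrum(traces, n_fft_policy, window=window)
    grid = traces.grid
    n_bins = spectra.magnitudes.shape[1]
    search = BandFilter(spectra.fr / 2, (n_bins - 1) * spectra.fr, preset="full-spectrum")
    cbf = np.zeros(grid.n_rois)
    reasons = np.full(grid.n_rois, REASON_NONE, dtype=object)
    for i in range(grid.n_rois):
        row = spectra.magnitudes[i]
        if row[1:].max(initial=0.0) <= static_tol:
            reasons[i] = REASON_STATIC
            continue
        peak_bin, _ = dominant_peak(row, search, spectra.fr)
        reason = noise_reject(row, peak_bin, peak_bin * spectra.fr, band,
                              snr_factor, static_tol=static_tol)
        if reason == REASON_NONE:
            cbf[i] = flanking_average(row, peak_bin, spectra.fr, mode=peak_mode)
        else:
            reasons[i] = reason
    shape = (grid.n_rows, grid.n_cols)
    return CbfMap(cbf=cbf.reshape(shape),
                  rejection_reason=reasons.reshape(shape).astype(str),
                  grid=grid, fr=spectra.fr, band=band)


def spectra_to_csv(spectra: SpectrumSet, roi_index: int, path) -> None:
    """Export one ROI's spectrum as ``bin,frequency_hz,magnitude`` rows."""
    row = spectra.magnitudes[roi_index]
    with open(path, "w", newline="") as fh:
        fh.write("bin,frequency_hz,magnitude\n")
        for k, mag in enumerate(row):
            fh.write(f"{k},{k * spectra.fr!r},{float(mag)!r}\n")
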