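"""Field-level CBF summaries, agreement statistics and report export.

Summary statistics are computed over accepted (nonzero) ROIs only: a
0 Hz entry is a rejection label, not a measurement, and averaging it in
would bias the field CBF downward. The static/rejected fractions are
reported as their own counts instead.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ValidationError
from .spectral import REASON_BELOW_SNR, REASON_NONE, REASON_OUT_OF_BAND, REASON_STATIC, CbfMap


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (spreadsheet convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(x, ndigits + 6))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CbfReport:
    """Summary of a :class:`~ciliafreq.spectral.CbfMap`.

    ``mean_cbf``/``median_cbf``/``modal_cbf``/``sd_cbf`` are ``nan``
    (undefined), never 0, when no ROI was accepted.
    """

    mean_cbf: float
    median_cbf: float
    modal_cbf: float
    sd_cbf: float
    n_total: int
    n_accepted: int
    n_static: int
    n_below_snr: int
    n_out_of_band: int
    histogram: list[tuple[float, int]]  # (lower bin edge Hz, count)
    heatmap: np.ndarray                 # grid-shaped CBF matrix
    hist_bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.n_total != self.n_accepted + self.n_static + self.n_below_snr + self.n_out_of_band:
            raise ValidationError("rejection counts do not sum to the ROI total")


@dataclass(frozen=True)
class AgreementResult:
    """Paired method-comparison statistics (Bland-Altman + regression)."""

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    r_squared: float
    t_statistic: float
    p_value: float
    n: int


def summarize(cbf_map: CbfMap, hist_bin_width: float = 1.0, *,
              include_zeros: bool = False) -> CbfReport:
    """Reduce a per-ROI map to field-level statistics and a histogram.

    ``include_zeros=True`` folds rejected (0 Hz) ROIs into the mean and
    median — the whole-field average some older tools report.
    """
    if hist_bin_width <= 0:
        raise ValidationError("hist_bin_width must be > 0")
    cbf = cbf_map.cbf.ravel()
    reasons = cbf_map.rejection_reason.ravel()
    accepted = cbf[reasons == REASON_NONE]
    n_total = cbf.size

    if accepted.size:
        edges = np.arange(0.0, accepted.max() + 2 * hist_bin_width, hist_bin_width)
        counts, _ = np.histogram(accepted, bins=edges)
        histogram = [(float(edges[i]), int(counts[i])) for i in range(len(counts))]
        modal = float(edges[int(np.argmax(counts))] + hist_bin_width / 2)
        stat_pool = cbf if include_zeros else accepted
        mean = float(np.mean(stat_pool))
        median = float(np.median(stat_pool))
        sd = float(np.std(accepted, ddof=1)) if accepted.size > 1 else 0.0
    else:
        histogram = []
        mean = median = modal = sd = math.nan

    return CbfReport(
        mean_cbf=mean, median_cbf=median, modal_cbf=modal, sd_cbf=sd,
        n_total=n_total,
        n_accepted=int(accepted.size),
        n_static=int(np.sum(reasons == REASON_STATIC)),
        n_below_snr=int(np.sum(reasons == REASON_BELOW_SNR)),
        n_out_of_band=int(np.sum(reasons == REASON_OUT_OF_BAND)),
        histogram=histogram, heatmap=cbf_map.cbf.copy(),
        hist_bin_width=hist_bin_width)


def direct_count_cbf(frame_rate: float, frames_elapsed: int, n_beats: int = 5) -> float:
    """Beat frequency from manually counted cycles during slow playback.

    ``frame_rate / frames_elapsed * n_beats`` — the number of frames
    spanning ``n_beats`` full beat cycles converted to beats per second.
    """
    if frame_rate <= 0:
        raise ValidationError(f"frame_rate must be > 0; got {frame_rate}")
    if frames_elapsed < 1:
        raise ValidationError(f"frames_elapsed must be >= 1; got {frames_elapsed}")
    if n_beats < 1:
        raise ValidationError(f"n_beats must be >= 1; got {n_beats}")
    return frame_rate / frames_elapsed * n_beats


def agreement(method_a, method_b) -> AgreementResult:
    """Compare two paired CBF series.

    Bland-Altman limits of agreement are the mean difference
    ± 1.96 x SD of the paired differences; ``r_squared`` comes from a
    least-squares regression of a on b; the t-test is paired,
    two-sided.
    """
    a = np.asarray(method_a, dtype=np.float64)
    b = np.asarray(method_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"paired series must be equal-length 1-D; got {a.shape}, {b.shape}")
    if a.size < 3:
        raise ValidationError(f"need at least 3 pairs; got {a.size}")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r_squared = 1.0 if np.allclose(diff, diff[0]) else 0.0
    else:
        r_squared = float(stats.linregress(b, a).rvalue ** 2)
    if np.allclose(diff, diff[0]):
        # zero-variance differences: t-test degenerate
        t_stat = math.inf if abs(mean_diff) > 0 else 0.0
        p_val = 0.0 if abs(mean_diff) > 0 else 1.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return AgreementResult(
        mean_difference=mean_diff, sd_difference=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff, loa_high=mean_diff + 1.96 * sd_diff,
        r_squared=r_squared, t_statistic=t_stat, p_value=p_val, n=int(a.size))


def _fmt(x: float) -> str:
    return "NA" if (isinstance(x, float) and math.isnan(x)) else f"{round_half_up(x, 2):.2f}"


def export_report(report: CbfReport, cbf_map: CbfMap, out_dir) -> dict[str, Path]:
    """Write per-ROI, summary and histogram CSVs plus a heatmap PNG.

    Heatmap follows the darker-is-faster convention. File contents are
    deterministic for identical inputs. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = cbf_map.grid
    paths = {}

    per_roi = out_dir / "cbf_per_roi.csv"
    with open(per_roi, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["roi_row", "roi_col", "cbf_hz", "reason"])
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                w.writerow([r + 1, c + 1, repr(float(cbf_map.cbf[r, c])),
                            cbf_map.rejection_reason[r, c]])
    paths["per_roi"] = per_roi

    summary = out_dir / "summary.csv"
    with open(summary, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["metric", "value"])
        w.writerow(["mean_cbf_hz", _fmt(report.mean_cbf)])
        w.writerow(["median_cbf_hz", _fmt(report.median_cbf)])
        w.writerow(["modal_cbf_hz", _fmt(report.modal_cbf)])
        w.writerow(["sd_cbf_hz", _fmt(report.sd_cbf)])
        w.writerow(["n_total", report.n_total])
        w.writerow(["n_accepted", report.n_accepted])
        w.writerow(["n_static", report.n_static])
        w.writerow(["n_below_snr", report.n_below_snr])
        w.writerow(["n_out_of_band", report.n_out_of_band])
        w.writerow(["frequency_resolution_hz", repr(float(cbf_map.fr))])
        w.writerow(["band_hz", f"{cbf_map.band.f_min}-{cbf_map.band.f_max}"])
        if report.n_accepted == 0:
            w.writerow(["warning", "no ROI accepted; statistics undefined"])
    paths["summary"] = summary

    hist = out_dir / "histogram.csv"
    with open(hist, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["bin_low_hz", "bin_high_hz", "count"])
        for edge, count in report.histogram:
            w.writerow([repr(edge), repr(edge + report.hist_bin_width), count])
    paths["histogram"] = hist

    heatmap = out_dir / "heatmap.png"
    _write_heatmap(cbf_map, heatmap)
    paths["heatmap"] = heatmap
    return paths


def _write_heatmap(cbf_map: CbfMap, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    vmax = cbf_map.cbf.max()
    im = ax.imshow(cbf_map.cbf, cmap="Greys", vmin=0.0,
                   vmax=vmax if vmax > 0 else 1.0, interpolation="nearest")
    ax.set_xlabel("ROI column")
    ax.set_ylabel("ROI row")
    ax.set_title("CBF (Hz) — darker = faster")
    fig.colorbar(im, ax=ax, label="CBF (Hz)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
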