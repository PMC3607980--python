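# ciliafreq

Ciliary beat frequency (CBF) analysis from high-speed video microscopy.

A recording is partitioned into a rectangular grid of up to 40×40 regions of
interest (ROIs), the mean pixel intensity of each ROI is tracked over time,
and each trace's dominant frequency is estimated from its FFT magnitude
spectrum. A peak is accepted only if it exceeds 3× the low-frequency
background and lies inside a physiologically plausible band (respiratory
3–20 Hz, ependymal 3–60 Hz); otherwise the ROI is reported as 0 Hz with a
rejection reason (`static`, `below_snr`, `out_of_band`). Accepted peaks are
refined to sub-bin precision with a magnitude-weighted average over the peak
and its two flanking bins.

The package also ships a synthetic-video generator with exact ground truth,
so the whole pipeline is testable without any real recording, plus
method-agreement utilities (Bland–Altman limits, paired t-test, r²).

## CLI

Batch-analyze one or more videos with identical settings:

```sh
ciliafreq analyze clip1.avi clip2.avi --fps 250 --grid 40 40 \
    --band respiratory --out results/
```

Per file this writes `cbf_per_roi.csv`, `summary.csv`, `histogram.csv`, a
`heatmap.png` (darker = faster) and the resolved `config.json`; a
`combined_summary.csv` collects one row per file (sorted by filename). A
failing file is logged and skipped; the exit code is nonzero if any file
failed. Useful flags: `--fmin/--fmax` (custom band), `--snr-factor`,
`--nfft {pow2,full}`, `--peak-mode {centroid,mean3,raw}`,
`--crop X Y W H` (spatial crop; the frequency resolution is untouched),
`--include-zeros`, `--export-traces`.

Generate a ground-truth synthetic recording:

```sh
ciliafreq simulate --spec spec.yaml --out video.avi --truth truth.csv
```

See `ciliafreq.synthetic.spec_from_yaml` for the YAML schema (frame rate,
frame count, oscillating regions with sine/sawtooth/square waveforms, noise,
optional lamp flicker, seed).

Compare two paired CBF series:

```sh
ciliafreq agreement a.csv b.csv --column cbf_hz
```

## Library

```python
import ciliafreq as cf

stack = cf.read_video("clip.avi", frame_rate_override=250)
grid = cf.make_grid(stack.height, stack.width, 40, 40)
traces = cf.extract_traces(stack, grid)
cbf_map = cf.compute_cbf(traces, cf.BandFilter.from_preset("respiratory"))
report = cf.summarize(cbf_map)
print(report.mean_cbf, report.n_static)
```

`frequency_resolution(frame_rate, n_frames)` gives the spectral bin spacing
(e.g. 120 fps / 128 frames → 0.94 Hz); `direct_count_cbf` converts manually
counted beat cycles to Hz.

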