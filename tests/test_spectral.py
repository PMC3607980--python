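import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliafreq.errors import ValidationError
from ciliafreq.roi_traces import extract_traces, make_grid
from ciliafreq.spectral import (BandFilter, compute_cbf, compute_spectrum,
                                dominant_peak, flanking_average,
                                frequency_resolution, noise_reject, spectra_to_csv)
from ciliafreq.synthetic import RegionSpec, SyntheticSpec, generate_video
from ciliafreq.video_io import crop

from conftest import brute_force_dft_mag


class TestFrequencyResolution:
    def test_paper_guidance_setting(self):
        assert round(frequency_resolution(120, 128), 2) == 0.94

    @pytest.mark.parametrize("rate,n,expected", [
        (250, 512, 0.48828125),
        (500, 1024, 0.48828125),
    ])
    def test_direct_arithmetic(self, rate, n, expected):
        assert frequency_resolution(rate, n) == expected

    @pytest.mark.parametrize("rate,n", [(0, 128), (-10, 128), (120, 1), (120, 0)])
    def test_invalid_inputs(self, rate, n):
        with pytest.raises(ValidationError):
            frequency_resolution(rate, n)


class TestComputeSpectrum:
    def test_constant_trace_all_zero(self, single_trace):
        spectra = compute_spectrum(single_trace(np.full(64, 13.0)))
        np.testing.assert_allclose(spectra.magnitudes, 0.0, atol=1e-9)

    def test_on_bin_sinusoid_magnitude(self, single_trace):
        n_fft, amp, k = 256, 7.5, 20
        t = np.arange(n_fft)
        trace = 100 + amp * np.sin(2 * np.pi * k * t / n_fft)
        spectra = compute_spectrum(single_trace(trace))
        assert spectra.magnitudes[0, k] == pytest.approx(n_fft * amp / 2, rel=1e-9)
        others = np.delete(spectra.magnitudes[0], k)
        assert others.max() < 1e-6 * spectra.magnitudes[0, k]

    @pytest.mark.parametrize("n", [16, 100, 512])
    def test_matches_brute_force_dft(self, single_trace, n):
        rng = np.random.default_rng(n)
        trace = rng.random(n) * 200
        spectra = compute_spectrum(single_trace(trace), n_fft_policy="full")
        np.testing.assert_allclose(spectra.magnitudes[0], brute_force_dft_mag(trace),
                                   rtol=1e-9, atol=1e-6)

    def test_pow2_truncation(self, single_trace):
        spectra = compute_spectrum(single_trace(np.random.default_rng(0).random(700)))
        assert spectra.n_fft == 512
        assert spectra.magnitudes.shape[1] == 257

    def test_fr_is_rate_over_nfft(self, single_trace):
        spectra = compute_spectrum(single_trace(np.zeros(512), frame_rate=250.0))
        assert spectra.fr == 250.0 / 512

    def test_short_trace_rejected(self, single_trace):
        with pytest.raises(ValidationError):
            compute_spectrum(single_trace(np.zeros(3)))

    def test_spectrum_csv_export(self, single_trace, tmp_path):
        spectra = compute_spectrum(single_trace(np.random.default_rng(1).random(64)))
        path = tmp_path / "spec.csv"
        spectra_to_csv(spectra, 0, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "bin,frequency_hz,magnitude"
        assert len(lines) == 34  # header + 33 bins


class TestDominantPeak:
    def test_unique_maximum(self):
        mags = np.zeros(100)
        mags[24] = 50.0
        assert dominant_peak(mags, BandFilter(3, 20), fr=0.5) == (24, 50.0)

    def test_tie_breaks_toward_lower_bin(self):
        mags = np.zeros(100)
        mags[10] = mags[30] = 9.0
        assert dominant_peak(mags, BandFilter(3, 20), fr=0.5)[0] == 10

    def test_42hz_sinusoid_against_oracle(self):
        # 500 fps, 512 frames -> fr = 0.9765625; oracle-derived peak bin 43
        t = np.arange(512) / 500
        trace = 100 + 50 * np.sin(2 * np.pi * 42 * t)
        mags = brute_force_dft_mag(trace)
        fr = 500 / 512
        bin_, _ = dominant_peak(mags, BandFilter(3, 60), fr)
        assert bin_ == 43
        assert bin_ * fr == pytest.approx(41.99, abs=0.01)

    def test_empty_band_rejected(self):
        with pytest.raises(ValidationError):
            dominant_peak(np.zeros(8), BandFilter(100, 200), fr=0.5)

    def test_search_excludes_bins_outside_band(self):
        mags = np.zeros(100)
        mags[2] = 100.0   # below band
        mags[40] = 10.0   # in band (20 Hz at fr=0.5)
        assert dominant_peak(mags, BandFilter(3, 20), fr=0.5)[0] == 40


class TestFlankingAverage:
    def test_symmetric_flanks_keep_peak_frequency(self):
        mags = np.zeros(50)
        mags[19], mags[20], mags[21] = 5.0, 30.0, 5.0
        assert flanking_average(mags, 20, fr=0.5) == pytest.approx(10.0)

    def test_one_sided_flank_shifts_half_bin(self):
        mags = np.zeros(50)
        mags[20] = mags[21] = 8.0  # m_{k-1}=0, m_{k+1}=m_k
        assert flanking_average(mags, 20, fr=0.5) == pytest.approx(20.5 * 0.5)

    def test_off_bin_sinusoid_beats_raw_peak(self, single_trace):
        # 10 Hz between bins 20 and 21 at fr = 250/512
        t = np.arange(512) / 250
        trace = 100 + 50 * np.sin(2 * np.pi * 10.0 * t)
        spectra = compute_spectrum(single_trace(trace, frame_rate=250.0))
        peak_bin, _ = dominant_peak(spectra.magnitudes[0], BandFilter(3, 20), spectra.fr)
        est = flanking_average(spectra.magnitudes[0], peak_bin, spectra.fr)
        assert abs(est - 10.0) < spectra.fr / 2
        assert abs(est - 10.0) < abs(peak_bin * spectra.fr - 10.0)

    def test_edge_clamp_at_last_bin(self):
        mags = np.zeros(10)
        mags[9] = 4.0
        assert flanking_average(mags, 9, fr=1.0) == pytest.approx(9.0)

    def test_raw_and_mean3_modes(self):
        mags = np.zeros(50)
        mags[20], mags[21] = 8.0, 8.0
        assert flanking_average(mags, 20, fr=0.5, mode="raw") == 10.0
        assert flanking_average(mags, 20, fr=0.5, mode="mean3") == 10.0

    @settings(max_examples=50, deadline=None)
    @given(left=st.floats(0, 100), mid=st.floats(1e-3, 100), right=st.floats(0, 100),
           k=st.integers(1, 48))
    def test_centroid_stays_within_one_bin(self, left, mid, right, k):
        mags = np.zeros(50)
        mags[k - 1], mags[k], mags[k + 1] = left, mid, right
        est = flanking_average(mags, k, fr=0.5)
        assert (k - 1) * 0.5 <= est <= (k + 1) * 0.5


class TestNoiseReject:
    def band(self):
        return BandFilter.from_preset("respiratory")

    def test_all_zero_spectrum_is_static(self):
        assert noise_reject(np.zeros(64), 10, 5.0, self.band()) == "static"

    def test_snr_threshold_is_three_times_background(self):
        mags = np.zeros(64)
        mags[2] = 10.0  # background = 10
        mags[20] = 29.0
        assert noise_reject(mags, 20, 10.0, self.band()) == "below_snr"
        mags[20] = 31.0
        assert noise_reject(mags, 20, 10.0, self.band()) == "none"

    def test_exactly_three_times_rejected(self):
        mags = np.zeros(64)
        mags[1] = 10.0
        mags[20] = 30.0  # must be strictly greater
        assert noise_reject(mags, 20, 10.0, self.band()) == "below_snr"

    def test_out_of_band_low_frequency(self):
        # clean 2 Hz oscillation, respiratory band 3-20 Hz
        mags = np.zeros(64)
        mags[4] = 100.0
        assert noise_reject(mags, 4, 2.0, self.band()) == "out_of_band"

    def test_band_presets(self):
        assert BandFilter.from_preset("respiratory").f_max == 20.0
        assert BandFilter.from_preset("ependymal").f_max == 60.0
        with pytest.raises(ValidationError):
            BandFilter.from_preset("cardiac")

    def test_custom_snr_factor(self):
        mags = np.zeros(64)
        mags[3] = 10.0
        mags[20] = 45.0
        assert noise_reject(mags, 20, 10.0, self.band(), snr_factor=5.0) == "below_snr"
        assert noise_reject(mags, 20, 10.0, self.band(), snr_factor=4.0) == "none"


class TestComputeCbf:
    def test_half_oscillating_half_static(self, sine_stack):
        stack, _ = sine_stack(frequency=12.0)
        traces = extract_traces(stack, make_grid(80, 80, 8, 8))
        cbf_map = compute_cbf(traces, BandFilter.from_preset("respiratory"))
        left = cbf_map.cbf[:, :4]
        np.testing.assert_allclose(left, 12.0, atol=cbf_map.fr)
        assert np.all(cbf_map.rejection_reason[:, 4:] == "static")
        np.testing.assert_array_equal(cbf_map.cbf[:, 4:], 0.0)

    def test_ependymal_42hz(self):
        spec = SyntheticSpec(frame_rate=500, n_frames=512, height=40, width=40,
                             regions=(RegionSpec(rect=(0, 0, 40, 40), frequency=42.0,
                                                 amplitude=40.0, baseline=120.0),),
                             seed=0)
        stack, _ = generate_video(spec)
        traces = extract_traces(stack, make_grid(40, 40, 4, 4))
        cbf_map = compute_cbf(traces, BandFilter.from_preset("ependymal"))
        accepted = cbf_map.cbf[cbf_map.accepted]
        assert accepted.size == 16
        assert abs(accepted.mean() - 42.0) < cbf_map.fr

    def test_white_noise_mostly_rejected(self):
        spec = SyntheticSpec(frame_rate=250, n_frames=512, height=80, width=80,
                             noise_sd=5.0, baseline=100.0, seed=11)
        stack, _ = generate_video(spec)
        traces = extract_traces(stack, make_grid(80, 80, 8, 8))
        cbf_map = compute_cbf(traces, BandFilter.from_preset("respiratory"))
        assert np.mean(cbf_map.cbf == 0) >= 0.95
        assert np.sum(cbf_map.rejection_reason == "below_snr") > 0

    def test_zero_iff_rejected(self, sine_stack):
        stack, _ = sine_stack(frequency=12.0, noise_sd=2.0, seed=5)
        traces = extract_traces(stack, make_grid(80, 80, 8, 8))
        cbf_map = compute_cbf(traces, BandFilter.from_preset("respiratory"))
        np.testing.assert_array_equal(cbf_map.cbf == 0,
                                      cbf_map.rejection_reason != "none")

    def test_accepted_cbf_within_band_plus_one_bin(self, sine_stack):
        stack, _ = sine_stack(frequency=19.6, noise_sd=1.0, seed=2)
        band = BandFilter.from_preset("respiratory")
        traces = extract_traces(stack, make_grid(80, 80, 8, 8))
        cbf_map = compute_cbf(traces, band)
        accepted = cbf_map.cbf[cbf_map.accepted]
        assert accepted.size > 0
        assert np.all(accepted >= band.f_min - cbf_map.fr)
        assert np.all(accepted <= band.f_max + cbf_map.fr)

    def test_out_of_band_oscillation_rejected_not_remapped(self):
        spec = SyntheticSpec(frame_rate=250, n_frames=512, height=40, width=40,
                             regions=(RegionSpec(rect=(0, 0, 40, 40), frequency=2.0,
                                                 amplitude=40.0, baseline=120.0),),
                             seed=0)
        stack, _ = generate_video(spec)
        traces = extract_traces(stack, make_grid(40, 40, 4, 4))
        cbf_map = compute_cbf(traces, BandFilter.from_preset("respiratory"))
        assert np.all(cbf_map.cbf == 0)
        assert np.all(cbf_map.rejection_reason == "out_of_band")

    def test_cropping_preserves_surviving_roi_cbf(self, sine_stack):
        stack, _ = sine_stack(frequency=12.0)
        full_map = compute_cbf(extract_traces(stack, make_grid(80, 80, 8, 8)),
                               BandFilter.from_preset("respiratory"))
        cropped = crop(stack, (0, 0, 40, 80))  # keep the oscillating half
        crop_map = compute_cbf(extract_traces(cropped, make_grid(80, 40, 8, 4)),
                               BandFilter.from_preset("respiratory"))
        assert crop_map.fr == full_map.fr
        np.testing.assert_allclose(crop_map.cbf, full_map.cbf[:, :4], atol=1e-9)

    def test_doubling_frames_halves_fr_without_hurting_recovery(self):
        errs = {}
        for n_frames in (512, 1024):
            spec = SyntheticSpec(frame_rate=250, n_frames=n_frames, height=40, width=40,
                                 regions=(RegionSpec(rect=(0, 0, 40, 40), frequency=10.0,
                                                     amplitude=40.0, baseline=120.0),),
                                 seed=0)
            stack, _ = generate_video(spec)
            cbf_map = compute_cbf(extract_traces(stack, make_grid(40, 40, 4, 4)),
                                  BandFilter.from_preset("respiratory"))
            errs[n_frames] = (cbf_map.fr, np.abs(cbf_map.cbf[cbf_map.accepted] - 10.0).max())
        assert errs[1024][0] == errs[512][0] / 2
        assert errs[1024][1] <= errs[512][1]
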