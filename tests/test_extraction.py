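"""Subharmonic extraction: windowed-DFT oracle, band logic, frame averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapeifp import (
    AmplitudeSpectrum,
    RFFrameSet,
    ROISpec,
    ValidationError,
    band_amplitude_db,
    roi_amplitude_spectrum,
    roi_signal,
    subharmonic_measurement,
)
from shapeifp.synthetic import SyntheticTruth, gen_rf_frameset

F0 = 8.5e6
FS = 62.5e6


def windowed_dft_oracle(line, fs, n_fft):
    """Brute-force normalized Hanning-windowed DFT amplitude spectrum."""
    n = line.size
    w = np.hanning(n)
    x = line * w
    k = np.arange(n_fft // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n_fft)
    return np.abs(basis @ x) * 2.0 / w.sum()


class TestROISignal:
    def test_full_extent_roi_is_identity(self, tone_frameset):
        roi = ROISpec(0, tone_frameset.n_lines, 0, tone_frameset.n_samples)
        np.testing.assert_array_equal(
            roi_signal(tone_frameset, roi, 0), tone_frameset.samples[0])

    def test_minimal_roi_shape(self, tone_frameset):
        assert roi_signal(tone_frameset, ROISpec(0, 1, 0, 64), 0).shape == (1, 64)

    def test_out_of_range_roi_and_frame_raise(self, tone_frameset):
        with pytest.raises(IndexError):
            roi_signal(tone_frameset, ROISpec(0, 999, 0, 64), 0)
        with pytest.raises(IndexError):
            roi_signal(tone_frameset, ROISpec(0, 1, 0, 64), tone_frameset.n_frames)


class TestROIAmplitudeSpectrum:
    def test_matches_brute_force_windowed_dft(self):
        # tone exactly on a padded-grid bin: oracle agreement to 1e-6 relative
        n, n_fft = 256, 1024
        k = 70  # bin index on the padded grid
        f = k * FS / n_fft
        a = 0.031622776601  # 30 dB below unity... arbitrary known amplitude
        line = a * np.cos(2 * np.pi * f * np.arange(n) / FS + 0.3)
        spec = roi_amplitude_spectrum(line[None, :], FS)
        oracle = windowed_dft_oracle(line, FS, n_fft)
        np.testing.assert_allclose(spec.amps, oracle, rtol=1e-6, atol=1e-12)
        assert spec.amps[k] == pytest.approx(a, rel=1e-4)

    def test_identical_lines_average_to_single_line(self, rng):
        line = rng.normal(size=256)
        one = roi_amplitude_spectrum(line[None, :], FS)
        two = roi_amplitude_spectrum(np.tile(line, (2, 1)), FS)
        np.testing.assert_allclose(two.amps, one.amps, rtol=1e-12)

    def test_all_zero_input_gives_zero_spectrum(self):
        spec = roi_amplitude_spectrum(np.zeros((4, 128)), FS)
        assert not spec.amps.any()

    def test_short_window_rejected(self):
        with pytest.raises(ValidationError):
            roi_amplitude_spectrum(np.zeros((1, 32)), FS)


class TestBandAmplitude:
    def make_spec(self, tones, n=2048, fs=FS):
        # n = 2048 keeps the Hanning main lobe (~2 bins = 61 kHz) well
        # inside the 0.1 MHz margins these band-edge checks rely on
        t = np.arange(n) / fs
        line = sum(a * np.cos(2 * np.pi * f * t) for f, a in tones)
        return roi_amplitude_spectrum(line[None, :], fs)

    def test_tone_at_center_equals_global_peak(self):
        spec = self.make_spec([(F0 / 2, 1.0)])
        assert band_amplitude_db(spec, F0 / 2) == pytest.approx(
            20 * np.log10(spec.amps.max()))

    def test_band_edges_are_inclusive_of_inside_tone_only(self):
        inside = self.make_spec([(F0 / 2 + 0.4e6, 1.0)])
        outside = self.make_spec([(F0 / 2 + 0.6e6, 1.0)])
        assert band_amplitude_db(inside, F0 / 2) == pytest.approx(0.0, abs=0.2)
        # tone outside the 1 MHz band: only skirts remain, far below 0 dB
        assert band_amplitude_db(outside, F0 / 2) < -20.0

    def test_larger_of_two_tones_wins_by_6db(self):
        two = self.make_spec([(F0 / 2 - 0.2e6, 2.0), (F0 / 2 + 0.2e6, 1.0)])
        one = self.make_spec([(F0 / 2 + 0.2e6, 1.0)])
        drop = band_amplitude_db(two, F0 / 2) - band_amplitude_db(one, F0 / 2)
        assert drop == pytest.approx(20 * np.log10(2), abs=0.05)

    def test_band_outside_spectrum_rejected(self):
        spec = self.make_spec([(F0 / 2, 1.0)])
        with pytest.raises(ValidationError):
            band_amplitude_db(spec, spec.freqs[-1])

    def test_zero_band_warns_and_returns_minus_inf(self):
        spec = AmplitudeSpectrum(freqs=np.arange(128) * 1e5,
                                 amps=np.zeros(128), df=1e5)
        with pytest.warns(RuntimeWarning):
            assert band_amplitude_db(spec, 5e6) == -np.inf


class TestSubharmonicMeasurement:
    def test_programmed_tone_recovered(self, tone_frameset, roi):
        m = subharmonic_measurement(tone_frameset, roi)
        assert m.amp_db == pytest.approx(30.0, abs=0.1)
        assert m.n_frames_avg == 20
        assert m.f0 == F0

    def test_fundamental_band_recovers_programmed_fundamental(self, tone_frameset, roi):
        spec = roi_amplitude_spectrum(roi_signal(tone_frameset, roi, 0), FS)
        assert band_amplitude_db(spec, F0) == pytest.approx(55.0, abs=0.1)

    def test_single_frame_average_equals_that_frame(self, tone_frameset, roi):
        m1 = subharmonic_measurement(tone_frameset, roi, n_frames_avg=1)
        spec = roi_amplitude_spectrum(roi_signal(tone_frameset, roi, 0), FS)
        assert m1.amp_db == pytest.approx(band_amplitude_db(spec, F0 / 2))

    def test_too_few_frames_rejected(self, tone_frameset, roi):
        with pytest.raises(ValidationError):
            subharmonic_measurement(tone_frameset, roi, n_frames_avg=99)

    def test_frame_averaging_reduces_jitter_by_sqrt_n(self, roi):
        """With per-frame dB jitter sigma, the 20-frame mean has SE ~ sigma/sqrt(20)."""
        sigma = 0.5
        roi_small = ROISpec(4, 8, 64, 192)
        amps = []
        for seed in range(200):
            truth = SyntheticTruth(-0.15, 40.0, 0.0, seed=seed)
            fset = gen_rf_frameset(
                truth, roi_small, n_lines=8, n_samples=256,
                components=[(F0 / 2, 30.0)], sigma_frame_db=sigma,
            )
            amps.append(subharmonic_measurement(fset, roi_small).amp_db)
        se = np.std(amps)
        assert se == pytest.approx(sigma / np.sqrt(20), rel=0.25)

    def test_absent_subharmonic_reads_noise_floor(self, roi, tone_components):
        # drop the subharmonic tone: band reading collapses to the noise floor
        comps = [c for c in tone_components if c[0] != F0 / 2]
        truth = SyntheticTruth(-0.15, 40.0, 0.0, seed=7)
        fset = gen_rf_frameset(truth, roi, components=comps, sigma_frame_db=0.0)
        m = subharmonic_measurement(fset, roi)
        assert m.amp_db < 30.0 - 35.0


@settings(max_examples=20, derandomize=True, deadline=None)
@given(k_db=st.floats(min_value=-30.0, max_value=30.0))
def test_scale_equivariance(k_db):
    """Scaling all RF samples by k shifts every dB output by 20*log10(k)."""
    roi = ROISpec(0, 4, 64, 192)
    truth = SyntheticTruth(-0.15, 40.0, 0.0, seed=3)
    base = gen_rf_frameset(truth, roi, n_frames=2, n_lines=4, n_samples=256,
                           components=[(F0 / 2, 10.0)], sigma_frame_db=0.0)
    k = 10.0 ** (k_db / 20.0)
    scaled = RFFrameSet(samples=base.samples * k, fs=base.fs, f0=base.f0,
                        pnp_kpa=base.pnp_kpa)
    m0 = subharmonic_measurement(base, roi, n_frames_avg=2)
    m1 = subharmonic_measurement(scaled, roi, n_frames_avg=2)
    # float32 sample storage limits exactness to ~1e-5 dB
    assert m1.amp_db - m0.amp_db == pytest.approx(k_db, abs=1e-4)
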