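"""Subharmonic amplitude extraction from beamformed RF frames.

Processing chain per frame: take the ROI sub-array, Hanning-window each scan
line along the time axis, FFT (zero-padded to the next power of two >= 4x
the window length), average the per-line amplitude spectra linearly, then
report the band amplitude at f0/2 in dB.  The final measurement is the mean
of the per-frame dB values over ``n_frames_avg`` frames (default 20).

Spectra are normalised by ``2 / sum(window)`` so that a tone of linear
amplitude *a* at a bin center produces a spectral peak of exactly *a* —
extraction is then calibrated in the same dB-re-1.0 convention used
everywhere else in the package.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    AmplitudeSpectrum,
    RFFrameSet,
    ROISpec,
    SubharmonicMeasurement,
    ValidationError,
    linear_to_db,
)
from .attenuation import next_pow2_fft_length

__all__ = [
    "roi_signal",
    "roi_amplitude_spectrum",
    "band_amplitude_db",
    "subharmonic_measurement",
]


def roi_signal(frameset: RFFrameSet, roi: ROISpec, frame_index: int) -> np.ndarray:
    """ROI sub-array ``[roi lines, roi samples]`` of one frame, unmodified."""
    if not 0 <= frame_index < frameset.n_frames:
        raise IndexError(
            f"frame_index {frame_index} out of range [0, {frameset.n_frames})"
        )
    roi.check_bounds(frameset.n_lines, frameset.n_samples)
    return frameset.samples[
        frame_index, roi.line_start:roi.line_end, roi.sample_start:roi.sample_end
    ]


def roi_amplitude_spectrum(roi_data: np.ndarray, fs: float) -> AmplitudeSpectrum:
    """Hanning-windowed, line-averaged amplitude spectrum of ROI data.

    Each line (row) is windowed and transformed separately; the per-line
    amplitude spectra are averaged linearly.  Lines within one ROI are
    treated as repeated looks at the same spectrum (Welch-style averaging in
    linear amplitude), distinct from the across-frame averaging which the
    acquisition protocol performs in dB.
    """
    roi_data = np.atleast_2d(np.asarray(roi_data, dtype=float))
    n = roi_data.shape[-1]
    if n < 64:
        raise ValidationError(f"ROI window must be >= 64 samples, got {n}")
    window = np.hanning(n)
    n_fft = next_pow2_fft_length(n)
    spectra = np.abs(np.fft.rfft(roi_data * window, n_fft, axis=-1))
    # 2/sum(w): a bin-centered tone of linear amplitude a reads back as a
    amps = spectra.mean(axis=0) * 2.0 / window.sum()
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps, df=fs / n_fft)


def band_amplitude_db(spec: AmplitudeSpectrum, f_center: float,
                      band_hz: float = 1e6, stat: str = "max") -> float:
    """Amplitude (dB) within the closed band ``f_center +/- band_hz/2``.

    ``stat="max"`` (default) reports the band maximum, robust to small
    shifts of the subharmonic peak inside the window; ``stat="mean_db"``
    reports the mean of the per-bin dB values instead.
    """
    lo = f_center - band_hz / 2.0
    hi = f_center + band_hz / 2.0
    if lo < spec.freqs[0] - 1e-9 or hi > spec.freqs[-1] + 1e-9:
        raise ValidationError(
            f"band [{lo:g}, {hi:g}] Hz outside spectral range "
            f"[{spec.freqs[0]:g}, {spec.freqs[-1]:g}] Hz"
        )
    in_band = (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)
    amps = spec.amps[in_band]
    if stat == "max":
        peak = float(amps.max())
        if peak == 0.0:
            warnings.warn("band amplitude is zero; returning -inf dB", RuntimeWarning)
            return float("-inf")
        return linear_to_db(peak)
    if stat == "mean_db":
        if np.any(amps == 0.0):
            warnings.warn("zero bins in band; returning -inf dB", RuntimeWarning)
            return float("-inf")
        return float(np.mean(20.0 * np.log10(amps)))
    raise ValidationError(f"unknown band statistic {stat!r}")


def subharmonic_measurement(frameset: RFFrameSet, roi: ROISpec,
                            n_frames_avg: int = 20, band_hz: float = 1e6,
                            frame_start: int = 0,
                            stat: str = "max") -> SubharmonicMeasurement:
    """Frame-averaged subharmonic (f0/2) amplitude of a frame set.

    The per-frame band amplitudes (dB) of ``n_frames_avg`` consecutive
    frames starting at ``frame_start`` are arithmetically averaged in dB,
    mirroring an acquisition protocol that records the average amplitude of
    repeated frames.
    """
    if n_frames_avg < 1:
        raise ValidationError("n_frames_avg must be >= 1")
    if frame_start + n_frames_avg > frameset.n_frames:
        raise ValidationError(
            f"requested frames [{frame_start}, {frame_start + n_frames_avg}) but "
            f"frame set has only {frameset.n_frames}"
        )
    roi.check_bounds(frameset.n_lines, frameset.n_samples)
    f_sub = frameset.f0 / 2.0
    per_frame = [
        band_amplitude_db(
            roi_amplitude_spectrum(roi_signal(frameset, roi, i), frameset.fs),
            f_sub, band_hz, stat=stat,
        )
        for i in range(frame_start, frame_start + n_frames_avg)
    ]
    return SubharmonicMeasurement(
        amp_db=float(np.mean(per_frame)),
        f0=frameset.f0,
        band_hz=band_hz,
        n_frames_avg=n_frames_avg,
        pnp_kpa=frameset.pnp_kpa,
        pressure_mmhg=frameset.ambient_mmhg,
        subject_id=str(frameset.meta.get("subject_id", "")),
    )
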