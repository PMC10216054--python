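"""Acoustic attenuation spectroscopy of microbubble suspensions.

A through-transmission setup records pulses through saline (reference) and
through the contrast-agent suspension (sample).  The attenuation coefficient
spectrum over a path of ``z`` cm is

    alpha(f) = (8.686 / z) * (ln S_ref(f) - ln S_sample(f))   [dB/cm]

with 8.686 = 20/ln(10), the amplitude-spectrum convention.  The microbubble
resonance frequency is the frequency of maximum attenuation; the optimal
transmit frequency for subharmonic generation is twice the resonance.
"""

from __future__ import annotations

import numpy as np

from .types import (
    AmplitudeSpectrum,
    AnalysisError,
    AttenuationSpectrum,
    PulseEnsemble,
    ValidationError,
)

__all__ = [
    "mean_amplitude_spectrum",
    "attenuation_spectrum",
    "resonance_frequency",
    "driving_frequency",
    "next_pow2_fft_length",
]

DB_PER_NEPER = 8.686  # 20 / ln(10)
DEFAULT_NOISE_FLOOR_DB = 40.0
DEFAULT_RESONANCE_BAND = (2.0e6, 6.0e6)


def next_pow2_fft_length(n: int, pad_factor: int = 4) -> int:
    """Smallest power of two >= pad_factor * n."""
    if n < 1:
        raise ValidationError("need n >= 1")
    return int(2 ** np.ceil(np.log2(pad_factor * n)))


def mean_amplitude_spectrum(ensemble: PulseEnsemble) -> AmplitudeSpectrum:
    """Amplitude spectrum of the coherent (time-domain) pulse average.

    Averaging the repeated pulses in the time domain before the FFT
    suppresses incoherent noise by ~10*log10(n_pulses) dB.  The averaged
    trace is zero-padded to the next power of two >= 4x its length, so the
    grid resolution is df = fs / N_fft.
    """
    traces = ensemble.traces
    mean_trace = traces.mean(axis=0)
    n = mean_trace.size
    n_fft = next_pow2_fft_length(n)
    amps = np.abs(np.fft.rfft(mean_trace, n_fft)) * 2.0 / n
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / ensemble.fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps, df=ensemble.fs / n_fft)


def attenuation_spectrum(sample: AmplitudeSpectrum,
                         reference: AmplitudeSpectrum,
                         z_cm: float,
                         noise_floor_db: float = DEFAULT_NOISE_FLOOR_DB) -> AttenuationSpectrum:
    """Attenuation coefficient alpha(f) = (8.686/z)(ln S_ref - ln S_sample).

    Positive where the sample attenuates.  Frequencies where either spectrum
    falls more than ``noise_floor_db`` below its own peak are masked invalid
    (alpha = NaN there): the log of near-noise bins is meaningless.
    """
    if z_cm <= 0:
        raise ValidationError("z_cm must be positive")
    if sample.freqs.shape != reference.freqs.shape or not np.allclose(
            sample.freqs, reference.freqs):
        raise ValidationError("sample and reference must share one frequency grid")

    s_ref = reference.amps
    s_sam = sample.amps
    valid = (
        (s_ref > s_ref.max() * 10.0 ** (-noise_floor_db / 20.0))
        & (s_sam > s_sam.max() * 10.0 ** (-noise_floor_db / 20.0))
    )
    alpha = np.full(s_ref.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha[valid] = (DB_PER_NEPER / z_cm) * (
            np.log(s_ref[valid]) - np.log(s_sam[valid])
        )
    if valid.any():
        band = (float(sample.freqs[valid].min()), float(sample.freqs[valid].max()))
    else:
        band = (float("nan"), float("nan"))
    return AttenuationSpectrum(
        freqs=sample.freqs, alpha=alpha, z_cm=z_cm, valid=valid, valid_band=band
    )


def resonance_frequency(attn: AttenuationSpectrum,
                        band: tuple[float, float] = DEFAULT_RESONANCE_BAND) -> float:
    """Frequency of maximum attenuation within ``band`` (Hz).

    Only valid (above-noise-floor) bins are searched.  Ties break toward the
    lowest frequency; a monotone spectrum therefore returns a band edge.
    Raises :class:`AnalysisError` when the band holds no valid bins.
    """
    f_lo, f_hi = band
    in_band = (attn.freqs >= f_lo) & (attn.freqs <= f_hi) & attn.valid
    if not in_band.any():
        raise AnalysisError(
            f"no valid attenuation estimates in band [{f_lo:g}, {f_hi:g}] Hz"
        )
    idx = np.flatnonzero(in_band)
    # argmax returns the first (lowest-frequency) maximum: the tie-break rule
    best = idx[np.argmax(attn.alpha[idx])]
    return float(attn.freqs[best])


def driving_frequency(f_res: float) -> float:
    """Optimal subharmonic transmit frequency: twice the resonance."""
    if f_res <= 0:
        raise ValidationError("resonance frequency must be positive")
    return 2.0 * f_res
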