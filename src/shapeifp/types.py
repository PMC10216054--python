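"""Shared domain types for the SHAPE interstitial-fluid-pressure pipeline.

All containers are plain dataclasses with eager invariant checking, so that a
malformed object fails at construction rather than deep inside a pipeline
stage.  Conventions used throughout the package:

* indices are 0-based, half-open; the time axis is always the *last* axis,
* amplitudes in dB are ``20*log10(linear)`` with an implicit unit reference,
* ambient/interstitial pressures are in mmHg, acoustic pressures in kPa
  (mechanical index is computed from MPa), frequencies in Hz.

Unit conversions are explicit named helpers (:func:`kpa_to_mpa` etc.) —
never implicit scale factors buried in formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "ShapeIfpError",
    "ValidationError",
    "FormatError",
    "AnalysisError",
    "SelectionError",
    "RFFrameSet",
    "ROISpec",
    "PulseEnsemble",
    "AmplitudeSpectrum",
    "AttenuationSpectrum",
    "SubharmonicMeasurement",
    "CalibrationModel",
    "SensitivityEntry",
    "TumorRecord",
    "RepeatResult",
    "CrossValReport",
    "kpa_to_mpa",
    "mpa_to_kpa",
    "hz_to_mhz",
    "mhz_to_hz",
    "db_to_linear",
    "linear_to_db",
]


class ShapeIfpError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ShapeIfpError, ValueError):
    """An input object or argument violates a documented invariant."""


class FormatError(ShapeIfpError, ValueError):
    """A file does not conform to the documented on-disk layout."""


class AnalysisError(ShapeIfpError, RuntimeError):
    """An analysis step cannot produce a result from valid inputs."""


class SelectionError(ShapeIfpError, RuntimeError):
    """No candidate satisfies the selection rule (e.g. significance gate)."""


# --------------------------------------------------------------------------
# unit helpers
# --------------------------------------------------------------------------

def kpa_to_mpa(p_kpa: float) -> float:
    """Convert kilopascal to megapascal."""
    return float(p_kpa) / 1000.0


def mpa_to_kpa(p_mpa: float) -> float:
    """Convert megapascal to kilopascal."""
    return float(p_mpa) * 1000.0


def hz_to_mhz(f_hz: float) -> float:
    """Convert hertz to megahertz."""
    return float(f_hz) / 1e6


def mhz_to_hz(f_mhz: float) -> float:
    """Convert megahertz to hertz."""
    return float(f_mhz) * 1e6


def db_to_linear(a_db: float) -> float:
    """Amplitude in dB (re 1.0) to linear amplitude."""
    return float(10.0 ** (a_db / 20.0))


def linear_to_db(a_lin: float) -> float:
    """Linear amplitude to dB re 1.0.  Returns ``-inf`` for zero."""
    if a_lin < 0:
        raise ValidationError(f"linear amplitude must be >= 0, got {a_lin}")
    if a_lin == 0:
        return -math.inf
    return float(20.0 * math.log10(a_lin))


# --------------------------------------------------------------------------
# acquisition containers
# --------------------------------------------------------------------------

@dataclass
class RFFrameSet:
    """Beamformed RF frames plus the acquisition metadata needed downstream.

    Parameters
    ----------
    samples
        Real-valued array ``[n_frames, n_lines, n_samples]`` in arbitrary
        linear units (beamformer output).
    fs
        Sampling rate in Hz.  Must exceed ``2*f0`` so that both the
        fundamental and the subharmonic sit below Nyquist.
    f0
        Transmit center frequency in Hz; the subharmonic lives at ``f0/2``.
    n_cycles
        Transmit tone-burst cycle count (a long burst is needed for stable
        subharmonic generation; the acquisitions emulated here use 16).
    pnp_kpa
        Peak-negative acoustic pressure at the focus, kPa (hydrophone
        calibrated).
    ambient_mmhg
        Optional ambient/IFP pressure label for this acquisition, mmHg.
    sound_speed
        Assumed speed of sound, m/s.
    meta
        Free-form annotations (e.g. the synthetic ground truth).
    """

    samples: np.ndarray
    fs: float
    f0: float
    n_cycles: int = 16
    pnp_kpa: float = 555.0
    ambient_mmhg: Optional[float] = None
    sound_speed: float = 1540.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 3:
            raise ValidationError(
                f"samples must be [n_frames, n_lines, n_samples], got ndim={self.samples.ndim}"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not self.fs > 2.0 * self.f0:
            raise ValidationError(
                f"fs={self.fs:g} Hz must exceed 2*f0={2 * self.f0:g} Hz (Nyquist)"
            )
        if not self.pnp_kpa > 0:
            raise ValidationError("pnp_kpa must be positive")
        if not np.isfinite(self.samples).all():
            raise ValidationError("RF samples contain non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_lines(self) -> int:
        return int(self.samples.shape[1])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[2])


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest, 0-based half-open indices.

    ``[line_start, line_end)`` selects scan lines, ``[sample_start,
    sample_end)`` selects time samples.  The time window must be at least 64
    samples so the spectral estimate is meaningful.
    """

    line_start: int
    line_end: int
    sample_start: int
    sample_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.line_start < self.line_end):
            raise ValidationError("require 0 <= line_start < line_end")
        if not (0 <= self.sample_start < self.sample_end):
            raise ValidationError("require 0 <= sample_start < sample_end")
        if self.n_window_samples < 64:
            raise ValidationError(
                f"ROI time window must be >= 64 samples, got {self.n_window_samples}"
            )

    @property
    def n_lines(self) -> int:
        return self.line_end - self.line_start

    @property
    def n_window_samples(self) -> int:
        return self.sample_end - self.sample_start

    def check_bounds(self, n_lines: int, n_samples: int) -> None:
        """Raise IndexError if the ROI does not fit inside a frame."""
        if self.line_end > n_lines:
            raise IndexError(
                f"ROI line_end={self.line_end} exceeds n_lines={n_lines}"
            )
        if self.sample_end > n_samples:
            raise IndexError(
                f"ROI sample_end={self.sample_end} exceeds n_samples={n_samples}"
            )


@dataclass
class PulseEnsemble:
    """Repeated through-transmission pulses for attenuation measurement.

    ``role`` distinguishes the reference acquisition (saline only) from the
    sample acquisition (microbubble suspension); ``z_cm`` is the acoustic
    path length through the suspension.
    """

    traces: np.ndarray
    fs: float
    role: str
    z_cm: float

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[0] < 1:
            raise ValidationError("need n_pulses >= 1")
        if self.role not in ("reference", "sample"):
            raise ValidationError(f"role must be 'reference' or 'sample', got {self.role!r}")
        if not self.z_cm > 0:
            raise ValidationError("z_cm must be positive")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    @property
    def n_pulses(self) -> int:
        return int(self.traces.shape[0])


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum on a uniform ascending frequency grid."""

    freqs: np.ndarray
    amps: np.ndarray
    df: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        if self.freqs.shape != self.amps.shape:
            raise ValidationError("freqs and amps must have the same length")
        if self.freqs.size >= 2:
            steps = np.diff(self.freqs)
            if not np.all(steps > 0) or not np.allclose(steps, steps[0]):
                raise ValidationError("frequency grid must be uniform and ascending")
        if not np.isfinite(self.amps).all() or np.any(self.amps < 0):
            raise ValidationError("amplitudes must be finite and non-negative")


@dataclass
class AttenuationSpectrum:
    """Attenuation coefficient spectrum α(f) in dB/cm over path ``z_cm``.

    ``valid`` marks frequencies where both input spectra were above the
    noise-floor threshold; ``alpha`` is NaN elsewhere.  ``valid_band`` is the
    (lowest, highest) valid frequency.
    """

    freqs: np.ndarray
    alpha: np.ndarray
    z_cm: float
    valid: np.ndarray
    valid_band: tuple[float, float]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.freqs.shape == self.alpha.shape == self.valid.shape):
            raise ValidationError("freqs, alpha and valid must share a shape")
        if not np.isfinite(self.alpha[self.valid]).all():
            raise ValidationError("alpha must be finite wherever marked valid")


# --------------------------------------------------------------------------
# measurement / model / report records
# --------------------------------------------------------------------------

@dataclass
class SubharmonicMeasurement:
    """Frame-averaged subharmonic amplitude for one acquisition condition."""

    amp_db: float
    f0: float
    band_hz: float = 1e6
    n_frames_avg: int = 1
    pnp_kpa: float = 555.0
    pressure_mmhg: Optional[float] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.band_hz > 0:
            raise ValidationError("band_hz must be positive")
        if self.n_frames_avg < 1:
            raise ValidationError("n_frames_avg must be >= 1")
        if not math.isfinite(self.amp_db):
            raise ValidationError("amp_db must be finite")


@dataclass
class CalibrationModel:
    """Fitted line amp_db = intercept + slope * pressure_mmhg.

    ``sensitivity`` is the magnitude of the slope (dB/mmHg); ``r`` and ``p``
    are the Pearson correlation and its two-sided significance from the
    t distribution with n-2 degrees of freedom.
    """

    slope: float
    intercept: float
    r: float
    p: float
    n: int
    slope_stderr: float = float("nan")
    sensitivity: float = field(init=False)

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"r={self.r} outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p={self.p} outside [0, 1]")
        if self.n < 3:
            raise ValidationError("need n >= 3")
        self.sensitivity = abs(self.slope)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, df = n-2)."""
        from scipy import stats

        half = stats.t.ppf(0.5 + level / 2.0, self.n - 2) * self.slope_stderr
        return (self.slope - half, self.slope + half)


@dataclass
class SensitivityEntry:
    """One row of the acoustic-pressure sensitivity table."""

    pnp_kpa: float
    mi: float
    sensitivity: float
    r: float
    p: float

    def __post_init__(self) -> None:
        if not self.mi > 0:
            raise ValidationError("mi must be positive")


@dataclass
class TumorRecord:
    """One tumor: geometry, reference IFP and its subharmonic measurements."""

    subject_id: str
    ifp_ref_mmhg: float
    measurements: list[SubharmonicMeasurement] = field(default_factory=list)
    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        dims = (self.a, self.b, self.c)
        if any(d is not None for d in dims):
            if any(d is None or d <= 0 for d in dims):
                raise ValidationError("tumor axes a, b, c must all be positive when present")
            expected = math.pi / 6.0 * self.a * self.b * self.c
            if self.volume is None:
                self.volume = expected
            elif not math.isclose(self.volume, expected, rel_tol=1e-6):
                raise ValidationError(
                    f"volume {self.volume} inconsistent with pi/6*a*b*c = {expected}"
                )

    @property
    def mean_amp_db(self) -> float:
        """Mean of this tumor's measurement amplitudes (dB)."""
        if not self.measurements:
            raise ValidationError(f"tumor {self.subject_id} has no measurements")
        return float(np.mean([m.amp_db for m in self.measurements]))


@dataclass
class RepeatResult:
    """Error statistics for one cross-validation repeat."""

    mae: float
    sd: float
    err_range: tuple[float, float]
    rmse: float
    p_paired: float
    model_idx: tuple[int, ...] = ()
    val_idx: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-12:
            raise ValidationError("mae cannot exceed rmse")
        if self.err_range[0] > self.err_range[1]:
            raise ValidationError("err_range must be (min, max)")


@dataclass
class CrossValReport:
    """Repeated random-split cross-validation summary."""

    repeats: list[RepeatResult]
    n_model: int
    n_val: int
    seed: int

    def __post_init__(self) -> None:
        if not self.repeats:
            raise ValidationError("need at least one repeat")

    @property
    def mean_mae(self) -> float:
        return float(np.mean([r.mae for r in self.repeats]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([r.rmse for r in self.repeats]))
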