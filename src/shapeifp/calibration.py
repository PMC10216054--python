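"""Amplitude–pressure calibration and acoustic-pressure optimisation.

The subharmonic amplitude of contrast microbubbles falls approximately
linearly with the ambient (hydrostatic or interstitial) pressure.  Fitting

    amp_db = intercept + slope * pressure_mmhg

by ordinary least squares gives the *pressure sensitivity* |slope| in
dB/mmHg.  Repeating the fit across transmit acoustic pressures yields a
sensitivity table from which the optimal operating point is the significant
entry with the greatest sensitivity: sensitivity peaks in the subharmonic
growth stage (roughly 0.3–0.6 MPa peak-negative pressure) and collapses in
saturation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import (
    CalibrationModel,
    SelectionError,
    SensitivityEntry,
    SubharmonicMeasurement,
    ValidationError,
    hz_to_mhz,
    kpa_to_mpa,
)

__all__ = [
    "fit_calibration",
    "pearson_p",
    "sensitivity_table",
    "select_optimal_pressure",
    "mechanical_index",
    "attenuation_loss_db",
    "compensation_multiplier",
]


def fit_calibration(measurements: Sequence[SubharmonicMeasurement],
                    pool_repeats: bool = True) -> CalibrationModel:
    """OLS fit of subharmonic amplitude (dB) on pressure (mmHg).

    With ``pool_repeats=True`` (default) repeated measurements at an
    identical pressure level are averaged before fitting, so that three
    repeated acquisitions at each of four levels enter the fit as n = 4
    points.  ``pool_repeats=False`` fits all rows individually.
    """
    if any(m.pressure_mmhg is None for m in measurements):
        raise ValidationError("every measurement needs a pressure label")
    if pool_repeats:
        groups: dict[float, list[float]] = defaultdict(list)
        for m in measurements:
            groups[float(m.pressure_mmhg)].append(m.amp_db)
        pressures = np.array(sorted(groups))
        amps = np.array([np.mean(groups[p]) for p in pressures])
    else:
        pressures = np.array([m.pressure_mmhg for m in measurements], dtype=float)
        amps = np.array([m.amp_db for m in measurements], dtype=float)

    n = pressures.size
    if n < 3:
        raise ValidationError(f"need >= 3 points to fit, got {n}")
    if np.unique(pressures).size < 2:
        raise ValidationError("degenerate design: all pressures identical")

    res = stats.linregress(pressures, amps)
    r = float(np.clip(res.rvalue, -1.0, 1.0))
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        p=float(res.pvalue),
        n=int(n),
        slope_stderr=float(res.stderr),
    )


def pearson_p(r: float, n: int) -> float:
    """Two-sided significance of a Pearson correlation (t, df = n-2).

    p = 2 * Pr(T_{n-2} > |r| sqrt(n-2) / sqrt(1-r^2)).  For n = 4 this
    collapses to the closed form p = 1 - |r|.  |r| = 1 returns 0.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def sensitivity_table(datasets: Mapping[float, Sequence[SubharmonicMeasurement]],
                      f0_hz: float,
                      pool_repeats: bool = True) -> list[SensitivityEntry]:
    """One sensitivity-table row per transmit acoustic pressure.

    Rows are sorted ascending in peak-negative pressure regardless of the
    mapping's order; each carries the mechanical index at ``f0_hz``, the
    fitted sensitivity |slope|, Pearson r and its two-sided p.
    """
    if not datasets:
        raise ValidationError("need at least one acoustic pressure")
    entries = []
    for pnp_kpa in sorted(datasets):
        try:
            model = fit_calibration(datasets[pnp_kpa], pool_repeats=pool_repeats)
        except ValidationError as exc:
            raise ValidationError(f"dataset at {pnp_kpa:g} kPa: {exc}") from exc
        entries.append(
            SensitivityEntry(
                pnp_kpa=float(pnp_kpa),
                mi=mechanical_index(kpa_to_mpa(pnp_kpa), hz_to_mhz(f0_hz)),
                sensitivity=model.sensitivity,
                r=model.r,
                p=model.p,
            )
        )
    return entries


def select_optimal_pressure(table: Sequence[SensitivityEntry],
                            alpha: float = 0.05) -> float:
    """Acoustic pressure (kPa) with the highest *significant* sensitivity.

    Entries with p >= alpha are excluded before maximising — a steep but
    non-significant fit is not a usable operating point.  Ties break toward
    the lower acoustic pressure.
    """
    if not table:
        raise ValidationError("empty sensitivity table")
    significant = [e for e in table if e.p < alpha]
    if not significant:
        raise SelectionError(
            f"no entry significant at alpha={alpha}; widen alpha or recollect"
        )
    best = max(sorted(significant, key=lambda e: e.pnp_kpa),
               key=lambda e: e.sensitivity)
    # max() keeps the first (lowest-kPa) element among exact ties
    return float(best.pnp_kpa)


def mechanical_index(pnp_mpa: float, f_mhz: float) -> float:
    """Mechanical index: peak-negative pressure (MPa) / sqrt(frequency, MHz)."""
    if pnp_mpa <= 0 or f_mhz <= 0:
        raise ValidationError("pressure and frequency must be positive")
    return float(pnp_mpa / np.sqrt(f_mhz))


def attenuation_loss_db(depth_cm: float, f_mhz: float,
                        coeff_db_per_cm_mhz: float) -> float:
    """One-way tissue attenuation loss: coeff * depth * frequency (dB).

    Typical soft-tissue coefficients: ~0.48 dB/cm/MHz for fat and
    ~0.75 dB/cm/MHz for breast parenchyma.
    """
    if depth_cm < 0 or f_mhz < 0 or coeff_db_per_cm_mhz < 0:
        raise ValidationError("all arguments must be >= 0")
    return float(coeff_db_per_cm_mhz * depth_cm * f_mhz)


def compensation_multiplier(loss_db: float) -> float:
    """Linear output-pressure multiplier restoring the in-situ target.

    A transmit path losing ``loss_db`` needs the source pressure raised by
    10^(loss_db/20) for the focus to see the intended peak-negative
    pressure.
    """
    if loss_db < 0:
        raise ValidationError("loss_db must be >= 0")
    return float(10.0 ** (loss_db / 20.0))
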