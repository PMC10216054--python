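"""IFP prediction from subharmonic amplitude and cross-validated agreement.

The calibration line is inverted to turn a measured subharmonic amplitude
into an interstitial-fluid-pressure estimate, and agreement with the
reference (needle-probe) IFP is quantified by repeated random-split
cross-validation: the cohort is split into a model group (fit) and a
validation group (predict), and per-repeat error statistics — mean absolute
error, its SD and range, RMSE, and a paired t-test of predicted vs
reference — are reported.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import fit_calibration
from .types import (
    CalibrationModel,
    CrossValReport,
    RepeatResult,
    SubharmonicMeasurement,
    TumorRecord,
    ValidationError,
)

__all__ = ["predict_ifp", "error_stats", "cross_validate", "tumor_volume"]

logger = logging.getLogger("shapeifp")

PLAUSIBLE_IFP_MMHG = (0.0, 100.0)


def predict_ifp(model: CalibrationModel, amp_db: float) -> float:
    """Invert the calibration: pressure = (amp_db - intercept) / slope.

    Predictions are never clipped (clipping would bias error statistics
    near the range edges); implausible values are only logged.
    """
    if model.slope == 0:
        raise ValidationError("cannot invert a zero-slope calibration")
    pred = (amp_db - model.intercept) / model.slope
    if not PLAUSIBLE_IFP_MMHG[0] <= pred <= PLAUSIBLE_IFP_MMHG[1]:
        logger.warning("predicted IFP %.2f mmHg outside plausible range", pred)
    return float(pred)


def error_stats(predicted: Sequence[float], reference: Sequence[float]) -> RepeatResult:
    """Agreement statistics between predicted and reference pressures.

    ``sd`` is the sample SD (ddof=1) of the *absolute* errors; ``p_paired``
    is the two-sided paired t-test of predicted vs reference (p = 1 when
    the signed differences have zero mean and zero spread).
    """
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape:
        raise ValidationError("predicted and reference must have equal length")
    if pred.size < 2:
        raise ValidationError("need >= 2 paired values")
    diff = pred - ref
    abs_err = np.abs(diff)
    if np.std(diff, ddof=1) == 0.0:
        p_paired = 1.0 if diff.mean() == 0.0 else 0.0
    else:
        p_paired = float(stats.ttest_rel(pred, ref).pvalue)
    return RepeatResult(
        mae=float(abs_err.mean()),
        sd=float(np.std(abs_err, ddof=1)),
        err_range=(float(abs_err.min()), float(abs_err.max())),
        rmse=float(np.sqrt(np.mean(diff ** 2))),
        p_paired=p_paired,
    )


def cross_validate(cohort: Sequence[TumorRecord], n_model: int = 20,
                   n_val: int = 10, repeats: int = 5, seed: int = 0) -> CrossValReport:
    """Repeated random 20/10-style split validation of the calibration.

    For each repeat a uniform random partition (repeat-specific substream of
    ``seed``) divides the cohort into model and validation groups.  The
    calibration is fitted on the model group — each tumor contributing the
    mean of its measurement amplitudes — and inverted to predict the
    validation group's IFPs.  Partition indices are recorded per repeat so
    any split can be reproduced exactly.
    """
    if len(cohort) != n_model + n_val:
        raise ValidationError(
            f"cohort size {len(cohort)} != n_model + n_val = {n_model + n_val}"
        )
    amps = np.array([rec.mean_amp_db for rec in cohort])
    refs = np.array([rec.ifp_ref_mmhg for rec in cohort])

    children = np.random.SeedSequence(seed).spawn(repeats)
    results = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(cohort))
        model_idx, val_idx = perm[:n_model], perm[n_model:]
        model_meas = [
            SubharmonicMeasurement(
                amp_db=float(amps[i]),
                f0=cohort[i].measurements[0].f0 if cohort[i].measurements else 8.5e6,
                pressure_mmhg=float(refs[i]),
                subject_id=cohort[i].subject_id,
            )
            for i in model_idx
        ]
        try:
            model = fit_calibration(model_meas, pool_repeats=False)
        except ValidationError as exc:
            raise ValidationError(f"repeat {rep}: {exc}") from exc
        pred = [predict_ifp(model, amps[i]) for i in val_idx]
        res = error_stats(pred, refs[val_idx])
        res.model_idx = tuple(int(i) for i in model_idx)
        res.val_idx = tuple(int(i) for i in val_idx)
        results.append(res)
    return CrossValReport(repeats=results, n_model=n_model, n_val=n_val, seed=seed)


def tumor_volume(a: float, b: float, c: float) -> float:
    """Ellipsoid-caliper tumor volume V = pi/6 * a * b * c (mm^3)."""
    if a <= 0 or b <= 0 or c <= 0:
        raise ValidationError("tumor axes must be positive")
    return float(math.pi / 6.0 * a * b * c)
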