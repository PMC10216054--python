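"""File formats, configuration and logging.

Two on-disk formats are defined and every other operation in the package
consumes only in-memory domain types:

* **RF container** — a single self-describing HDF5 file holding one
  :class:`~shapeifp.types.RFFrameSet`: dataset ``/rf`` (float32,
  ``[n_frames, n_lines, n_samples]``), required attributes ``fs_hz``,
  ``f0_hz``, ``n_cycles``, ``pnp_kpa``, ``sound_speed_mps``, optional
  ``ambient_mmhg`` and ``subject_id``, and an optional dataset ``/roi``
  (int64 ``[4]`` = line_start, line_end, sample_start, sample_end).
* **Measurement table** — a CSV with exactly the columns
  ``subject_id, pnp_kpa, pressure_mmhg, amp_db, f0_hz, band_hz,
  n_frames_avg``, one subharmonic measurement per row.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (
    FormatError,
    PulseEnsemble,
    RFFrameSet,
    ROISpec,
    SubharmonicMeasurement,
    ValidationError,
)

__all__ = [
    "read_rf_container",
    "write_rf_container",
    "read_pulse_ensemble",
    "write_pulse_ensemble",
    "read_measurement_table",
    "write_measurement_table",
    "measurements_to_frame",
    "load_config",
    "merge_config",
    "setup_logging",
    "log_stage",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = (
    "subject_id",
    "pnp_kpa",
    "pressure_mmhg",
    "amp_db",
    "f0_hz",
    "band_hz",
    "n_frames_avg",
)

_REQUIRED_ATTRS = ("fs_hz", "f0_hz", "n_cycles", "pnp_kpa", "sound_speed_mps")


# --------------------------------------------------------------------------
# RF container
# --------------------------------------------------------------------------

def write_rf_container(frameset: RFFrameSet, path: Union[str, Path],
                       roi: Optional[ROISpec] = None) -> Path:
    """Write a validated frame set to an HDF5 RF container.

    Round-trips bit-exactly: ``read_rf_container(write_rf_container(x))``
    reproduces the samples and metadata exactly.
    """
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rf", data=frameset.samples.astype(np.float32))
        h5.attrs["fs_hz"] = float(frameset.fs)
        h5.attrs["f0_hz"] = float(frameset.f0)
        h5.attrs["n_cycles"] = int(frameset.n_cycles)
        h5.attrs["pnp_kpa"] = float(frameset.pnp_kpa)
        h5.attrs["sound_speed_mps"] = float(frameset.sound_speed)
        if frameset.ambient_mmhg is not None:
            h5.attrs["ambient_mmhg"] = float(frameset.ambient_mmhg)
        if "subject_id" in frameset.meta:
            h5.attrs["subject_id"] = str(frameset.meta["subject_id"])
        if roi is not None:
            h5.create_dataset(
                "roi",
                data=np.array(
                    [roi.line_start, roi.line_end, roi.sample_start, roi.sample_end],
                    dtype=np.int64,
                ),
            )
    return path


def read_rf_container(path: Union[str, Path]) -> tuple[RFFrameSet, Optional[ROISpec]]:
    """Read an RF container; returns the frame set and the stored ROI, if any.

    Raises :class:`FormatError` naming the missing dataset/attribute, and
    :class:`ValidationError` if the stored metadata violates an invariant
    (e.g. sampling below Nyquist for the fundamental).
    """
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if "rf" not in h5:
            raise FormatError(f"{path}: missing dataset 'rf'")
        for attr in _REQUIRED_ATTRS:
            if attr not in h5.attrs:
                raise FormatError(f"{path}: missing required attribute {attr!r}")
        meta = {}
        if "subject_id" in h5.attrs:
            meta["subject_id"] = str(h5.attrs["subject_id"])
        frameset = RFFrameSet(
            samples=h5["rf"][...],
            fs=float(h5.attrs["fs_hz"]),
            f0=float(h5.attrs["f0_hz"]),
            n_cycles=int(h5.attrs["n_cycles"]),
            pnp_kpa=float(h5.attrs["pnp_kpa"]),
            ambient_mmhg=(float(h5.attrs["ambient_mmhg"])
                          if "ambient_mmhg" in h5.attrs else None),
            sound_speed=float(h5.attrs["sound_speed_mps"]),
            meta=meta,
        )
        roi = None
        if "roi" in h5:
            vals = [int(v) for v in h5["roi"][...]]
            roi = ROISpec(*vals)
    return frameset, roi


def write_pulse_ensemble(ensemble: PulseEnsemble, path: Union[str, Path]) -> Path:
    """Write a pulse ensemble (HDF5: dataset /traces, attrs fs_hz, role, z_cm)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("traces", data=np.asarray(ensemble.traces, dtype=np.float64))
        h5.attrs["fs_hz"] = float(ensemble.fs)
        h5.attrs["role"] = ensemble.role
        h5.attrs["z_cm"] = float(ensemble.z_cm)
    return path


def read_pulse_ensemble(path: Union[str, Path]) -> PulseEnsemble:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if "traces" not in h5:
            raise FormatError(f"{path}: missing dataset 'traces'")
        for attr in ("fs_hz", "role", "z_cm"):
            if attr not in h5.attrs:
                raise FormatError(f"{path}: missing required attribute {attr!r}")
        return PulseEnsemble(
            traces=h5["traces"][...],
            fs=float(h5.attrs["fs_hz"]),
            role=str(h5.attrs["role"]),
            z_cm=float(h5.attrs["z_cm"]),
        )


# --------------------------------------------------------------------------
# measurement table
# --------------------------------------------------------------------------

def measurements_to_frame(measurements: list[SubharmonicMeasurement]) -> pd.DataFrame:
    """Tabulate measurements with the canonical CSV column order."""
    rows = [
        {
            "subject_id": m.subject_id,
            "pnp_kpa": m.pnp_kpa,
            "pressure_mmhg": m.pressure_mmhg,
            "amp_db": m.amp_db,
            "f0_hz": m.f0,
            "band_hz": m.band_hz,
            "n_frames_avg": m.n_frames_avg,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def write_measurement_table(measurements: list[SubharmonicMeasurement],
                            path: Union[str, Path]) -> Path:
    path = Path(path)
    measurements_to_frame(measurements).to_csv(path, index=False)
    return path


def read_measurement_table(path: Union[str, Path]) -> list[SubharmonicMeasurement]:
    """Read a measurement CSV; one record per row, row order preserved.

    Unknown columns and non-numeric cells raise :class:`FormatError` with
    the offending column / row number (0-based data row).
    """
    path = Path(path)
    # keep_default_na=False: a literal "n/a" must be a parse error, not NaN
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(MEASUREMENT_COLUMNS)
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {sorted(unknown)}")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")

    out: list[SubharmonicMeasurement] = []
    numeric = ("pnp_kpa", "pressure_mmhg", "amp_db", "f0_hz", "band_hz", "n_frames_avg")
    for i, row in df.iterrows():
        vals = {}
        for col in numeric:
            raw = row[col]
            if col == "pressure_mmhg" and (pd.isna(raw) or raw == ""):
                vals[col] = None
                continue
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric value {raw!r} in column {col!r} at row {i}"
                ) from None
        out.append(
            SubharmonicMeasurement(
                amp_db=vals["amp_db"],
                f0=vals["f0_hz"],
                band_hz=vals["band_hz"],
                n_frames_avg=int(vals["n_frames_avg"]),
                pnp_kpa=vals["pnp_kpa"],
                pressure_mmhg=vals["pressure_mmhg"],
                subject_id=str(row["subject_id"]),
            )
        )
    return out


# --------------------------------------------------------------------------
# configuration and logging
# --------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> dict:
    """Load a JSON or YAML configuration file (keys mirror CLI flags)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    if path.suffix.lower() in (".yml", ".yaml"):
        loaded = yaml.safe_load(text)
        return loaded if loaded is not None else {}
    raise FormatError(f"{path}: unknown config format (expect .json/.yaml)")


def merge_config(cli_values: dict, config: dict) -> dict:
    """Merge config-file defaults under explicit CLI values; CLI wins."""
    merged = dict(config)
    merged.update({k: v for k, v in cli_values.items() if v is not None})
    return merged


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger("shapeifp")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


def log_stage(logger: logging.Logger, stage: str, **fields) -> None:
    """Emit one machine-parsable ``key=value`` summary line per stage."""
    parts = [f"stage={stage}"]
    for k, v in fields.items():
        if isinstance(v, float):
            v = f"{v:.6g}"
        parts.append(f"{k}={v}")
    logger.info(" ".join(parts))
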