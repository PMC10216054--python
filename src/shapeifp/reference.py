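"""Published reference values for the Sonazoid in vitro sweep at 8.5 MHz.

These are the reported per-acoustic-pressure fit summaries (peak-negative
pressure, fitted sensitivity, Pearson r over the four ambient-pressure
levels) for Sonazoid microbubbles driven at 8.5 MHz in a vessel phantom.
They serve as *inputs* to the selection and significance machinery — e.g.
recomputing each p value from its r with n = 4 and selecting the optimal
operating point — and as targets for synthetic parameter-recovery runs.
"""

from __future__ import annotations

from .calibration import mechanical_index, pearson_p
from .types import SensitivityEntry, hz_to_mhz, kpa_to_mpa

__all__ = [
    "REFERENCE_SWEEP_ROWS",
    "REFERENCE_SWEEP_N",
    "reference_sensitivity_table",
]

#: (pnp_kpa, sensitivity dB/mmHg, Pearson r) per acoustic pressure
REFERENCE_SWEEP_ROWS: tuple[tuple[float, float, float], ...] = (
    (292.0, 0.012, -0.862),
    (407.0, 0.123, -0.883),
    (555.0, 0.150, -0.966),
    (663.0, 0.068, -0.924),
    (746.0, 0.029, -0.999),
    (816.0, 0.028, -0.569),
)

#: ambient-pressure levels per fit (10, 20, 30, 40 mmHg)
REFERENCE_SWEEP_N = 4


def reference_sensitivity_table(f0_hz: float = 8.5e6) -> list[SensitivityEntry]:
    """Sensitivity table built from the reference rows.

    The mechanical index and the p value are *recomputed* here —
    MI from (pnp, f0) and p from (r, n=4) — not copied, so the table
    exercises the same code paths as a fitted one.
    """
    return [
        SensitivityEntry(
            pnp_kpa=pnp,
            mi=mechanical_index(kpa_to_mpa(pnp), hz_to_mhz(f0_hz)),
            sensitivity=sens,
            r=r,
            p=pearson_p(r, REFERENCE_SWEEP_N),
        )
        for pnp, sens, r in REFERENCE_SWEEP_ROWS
    ]
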