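"""Spike-in standard-curve calibration and inversion to circulating-tumor-cell
counts.

A classical calibration: ordinary least squares of luminescence on the known
spiked cell counts, then algebraic inversion of new readings through the
fitted line.  Readings at or below the intercept clamp to zero cells (blank
samples sit there) and are flagged.  Cell counts are normalized by the blood
sample volume (default 0.4 ml) to cells per ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CalibrationFit", "CTCEstimate", "fit_calibration", "estimate_ctc"]


@dataclass
class CalibrationFit:
    slope: float          # luminescence per cell
    intercept: float      # luminescence at zero cells
    r_squared: float
    residual_sd: float
    counts: np.ndarray    # design points used

    @property
    def n_points(self) -> int:
        return len(self.counts)


@dataclass
class CTCEstimate:
    cells: float
    cells_per_ml: float
    clamped: bool


def fit_calibration(counts, luminescence, force_zero_intercept: bool = False) -> CalibrationFit:
    """OLS fit of luminescence on spiked cell count.

    Requires >= 3 paired points with non-negative, non-constant counts.
    ``force_zero_intercept`` fits luminescence = slope * count instead.
    """
    counts = np.asarray(counts, dtype=float)
    lum = np.asarray(luminescence, dtype=float)
    if counts.shape != lum.shape:
        raise ValueError("counts and luminescence must be paired")
    if len(counts) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(counts)}")
    if (counts < 0).any():
        raise ValueError("negative cell counts in the calibration design")
    if np.ptp(counts) == 0:
        raise ValueError("calibration counts are all equal; slope is unidentifiable")
    if force_zero_intercept:
        slope = float((counts * lum).sum() / (counts**2).sum())
        intercept = 0.0
        fitted = slope * counts
        ss_res = float(((lum - fitted) ** 2).sum())
        ss_tot = float(((lum - lum.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = len(counts) - 1
    else:
        fit = stats.linregress(counts, lum)
        slope, intercept = float(fit.slope), float(fit.intercept)
        fitted = intercept + slope * counts
        ss_res = float(((lum - fitted) ** 2).sum())
        r2 = float(fit.rvalue**2)
        dof = len(counts) - 2
    residual_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r2)),
        residual_sd=residual_sd,
        counts=counts.copy(),
    )


def estimate_ctc(
    luminescence_reading: float, fit: CalibrationFit, sample_volume_ml: float = 0.4
) -> CTCEstimate:
    """Invert a luminescence reading through the standard curve.

    cells = (reading - intercept) / slope, clamped at 0 (flagged) for
    readings below the intercept; cells per ml divides by the sample volume.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive to invert readings")
    if sample_volume_ml <= 0:
        raise ValueError("sample volume must be positive")
    cells = (float(luminescence_reading) - fit.intercept) / fit.slope
    clamped = cells < 0
    if clamped:
        cells = 0.0
    return CTCEstimate(
        cells=cells, cells_per_ml=cells / sample_volume_ml, clamped=bool(clamped)
    )
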