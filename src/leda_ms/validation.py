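"""Validation plots: calculated vs expected isomer fraction.

Accuracy and precision of the deconvolution are summarized by regressing
the calculated fraction of an isomer on its nominal (expected) fraction
across a ladder of standard mixtures analyzed in replicate. A slope of 1
means 100% recognition accuracy; the residual standard error (SE-Lin) is
the precision on the fraction scale; |y-intercept| + 2·SE-Lin bounds the
smallest relative abundance the method can reliably recognize (95%
reasoning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .leda_core import RatioTable, peak_purity
from .signal_io import SampleRecord


@dataclass
class ValidationPlot:
    isomer_id: str
    expected: np.ndarray
    calculated: np.ndarray
    slope: float
    y_intercept: float
    r2: float
    se_lin: float           # residual standard error, fraction scale

    @property
    def detection_floor(self) -> float:
        """Smallest reliably recognizable fraction: |intercept| + 2·SE-Lin."""
        return abs(self.y_intercept) + 2.0 * self.se_lin


def build_validation_plot(
    expected, calculated, isomer_id: str = ""
) -> ValidationPlot:
    """OLS of calculated fraction on expected fraction."""
    x = np.asarray(expected, dtype=float).ravel()
    y = np.asarray(calculated, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("expected and calculated must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct expected levels")
    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    dof = len(x) - 2
    se_lin = float(np.sqrt(np.sum(residuals**2) / dof)) if dof > 0 else 0.0
    return ValidationPlot(
        isomer_id=isomer_id,
        expected=x,
        calculated=y,
        slope=float(fit.slope),
        y_intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        se_lin=se_lin,
    )


def run_mixture_validation(
    mixture_samples: list[SampleRecord],
    table: RatioTable,
    matrix: np.ndarray,
    window: tuple[float, float],
    transitions: list[str] | None = None,
    *,
    nonneg: bool = True,
    closure: bool = False,
) -> dict[str, ValidationPlot]:
    """Deconvolve every standard mixture and build one plot per isomer.

    Each sample must carry its nominal composition; replicate injections
    of the same mixture level enter the regressions as individual points.
    """
    if not mixture_samples:
        raise ValueError("no mixture samples supplied")
    expected: dict[str, list[float]] = {iso: [] for iso in table.isomer_ids}
    calculated: dict[str, list[float]] = {iso: [] for iso in table.isomer_ids}
    for rec in mixture_samples:
        if rec.nominal_composition is None:
            raise ValueError(
                f"sample {rec.sample_id!r} has no nominal composition"
            )
        result = peak_purity(
            rec, matrix, table, window, transitions, nonneg=nonneg, closure=closure
        )
        for iso in table.isomer_ids:
            expected[iso].append(rec.nominal_composition.get(iso, 0.0))
            calculated[iso].append(result.fractions[iso])
    return {
        iso: build_validation_plot(expected[iso], calculated[iso], iso)
        for iso in table.isomer_ids
    }
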