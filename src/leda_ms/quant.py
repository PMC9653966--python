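"""Calibration, LOD/LOQ, matrix effect / recovery, and isomer quantitation.

Quantitation uses peak-area ratios (PAR) of the analyte signal to an
internal standard (IS), regressed against nominal concentration to give a
calibration line. Detection limits follow the standard-error-of-response
and slope approach: LOD = 3.3·Y-SE/slope and LOQ = 10·Y-SE/slope, where
Y-SE is the standard error of the regression's y-intercept. These
ICH-style multipliers are the defaults and can be overridden.

For co-eluting isomers the deconvolved fractions split the shared
precursor-ion (Ri) peak area, after which each isomer is quantified on
its own precursor-ion calibration curve exactly as a single analyte
would be.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .leda_core import DeconvolutionResult, integrate_peak
from .signal_io import SampleRecord

LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


@dataclass
class CalibrationCurve:
    analyte_id: str
    quant_transition: str
    levels: np.ndarray          # ng/mL
    pars: np.ndarray            # one PAR per calibration point
    slope: float                # PAR per ng/mL
    intercept: float            # PAR
    y_se: float                 # SE of the intercept (Y-SE)
    r2: float
    lod: float                  # ng/mL
    loq: float                  # ng/mL

    def concentration(self, par: float) -> float:
        return (par - self.intercept) / self.slope


@dataclass
class QuantResult:
    analyte_id: str
    par: float
    concentration: float        # ng/mL
    source_fraction: float      # deconvolved share of the Ri signal (1.0 if pure)
    below_loq: bool
    below_lod: bool
    concentration_um: float | None = None


def compute_par(analyte_area: float, is_area: float) -> float:
    """Peak-area ratio of analyte to internal standard."""
    if is_area <= 0:
        raise ValueError(
            "internal-standard area is zero — failed injection or missing IS"
        )
    return float(analyte_area) / float(is_area)


def fit_calibration(
    levels,
    pars,
    analyte_id: str = "",
    quant_transition: str = "",
    lod_multiplier: float = LOD_MULTIPLIER,
    loq_multiplier: float = LOQ_MULTIPLIER,
) -> CalibrationCurve:
    """Unweighted OLS of PAR on nominal concentration over all replicates.

    ``pars`` may be a flat vector matching ``levels``, or a 2-D array of
    shape (n_levels, n_replicates); replicate points enter the regression
    individually.
    """
    levels = np.asarray(levels, dtype=float).ravel()
    pars = np.asarray(pars, dtype=float)
    if pars.ndim == 2:
        if pars.shape[0] != len(levels):
            raise ValueError("replicate PAR array must have one row per level")
        x = np.repeat(levels, pars.shape[1])
        y = pars.ravel()
    else:
        if pars.shape != levels.shape:
            raise ValueError("flat PAR vector must match levels in length")
        x, y = levels, pars
    if len(np.unique(levels)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    if np.ptp(x) == 0:
        raise ValueError("calibration levels have zero variance")

    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if not np.isfinite(slope) or slope == 0:
        raise ValueError("degenerate calibration: zero or non-finite slope")
    y_se = float(fit.intercept_stderr)
    return CalibrationCurve(
        analyte_id=analyte_id,
        quant_transition=quant_transition,
        levels=levels,
        pars=y,
        slope=slope,
        intercept=float(fit.intercept),
        y_se=y_se,
        r2=float(fit.rvalue**2),
        lod=lod_multiplier * y_se / abs(slope),
        loq=loq_multiplier * y_se / abs(slope),
    )


def quantify_isomers(
    sample: SampleRecord,
    decon: DeconvolutionResult,
    curves: dict[str, CalibrationCurve],
    window: tuple[float, float],
    molecular_weights: dict[str, float] | None = None,
) -> list[QuantResult]:
    """Assign the deconvolved share of the Ri area to each isomer and quantify.

    Per isomer: assigned area = fraction × area(Ri); PAR = assigned / IS
    area; concentration from the isomer's precursor-ion calibration curve.
    With ``molecular_weights`` (g/mol) the concentration is also expressed
    in µM. Concentrations below the curve's LOQ/LOD are flagged, not
    suppressed.
    """
    missing = [iso for iso in decon.fractions if iso not in curves]
    if missing:
        raise KeyError(f"no calibration curve for isomers {missing}")
    ri_area = integrate_peak(sample.trace_by_role("Ri"), window)
    is_area = integrate_peak(sample.trace_by_role("IS"), window)

    results = []
    for isomer, fraction in decon.fractions.items():
        curve = curves[isomer]
        par = compute_par(fraction * ri_area, is_area)
        conc = max(curve.concentration(par), 0.0)
        conc_um = None
        if molecular_weights is not None:
            mw = molecular_weights.get(isomer)
            if mw is not None:
                conc_um = conc / mw  # ng/mL / (g/mol) = µmol/L
        results.append(
            QuantResult(
                analyte_id=isomer,
                par=par,
                concentration=conc,
                source_fraction=fraction,
                # 1e-9 ng/mL guard: keeps the flags stable against floating-
                # point residue when an ideal (zero-Y-SE) curve puts LOD at 0
                below_loq=conc <= curve.loq + 1e-9,
                below_lod=conc <= curve.lod + 1e-9,
                concentration_um=conc_um,
            )
        )
    return results


def matrix_effect(area_set_b: float, area_set_a: float) -> float:
    """ME(%) = 100·B/A: post-extraction-spiked plasma vs neat solvent."""
    if area_set_a <= 0:
        raise ValueError("set A (neat solvent) area must be positive")
    return 100.0 * float(area_set_b) / float(area_set_a)


def recovery(area_set_c: float, area_set_b: float) -> float:
    """RE(%) = 100·C/B: pre-extraction spike vs post-extraction spike."""
    if area_set_b <= 0:
        raise ValueError("set B (post-extraction spike) area must be positive")
    return 100.0 * float(area_set_c) / float(area_set_b)
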