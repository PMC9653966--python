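"""Energy-resolved MS breakdown curves and diagnostic product-ion selection.

A breakdown curve reports, for each ion observed in a CV-stepped series of
product-ion scans, its fragmentation yield: the scan-averaged intensity at
each collision voltage divided by the maximum intensity the intact
precursor reaches anywhere in the sweep. On that normalization the
precursor's own curve peaks at exactly 1, while an efficiently formed
fragment can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import ERMSTable


@dataclass
class BreakdownCurveSet:
    compound_id: str
    precursor_mz: float
    collision_voltages: np.ndarray
    yield_curves: dict[float, np.ndarray]


def build_breakdown_curves(erms: ERMSTable, precursor_mz: float) -> BreakdownCurveSet:
    """Normalize every ion's CV profile to the precursor's maximum intensity.

    Raises if the precursor is absent from the table or never detected
    (the normalization is then undefined).
    """
    precursor_mz = float(precursor_mz)
    if precursor_mz not in erms.ion_intensities:
        raise ValueError(
            f"precursor m/z {precursor_mz:g} not in ERMS table for "
            f"{erms.compound_id!r}"
        )
    if len(erms.collision_voltages) < 2:
        raise ValueError("need at least 2 CV steps to build breakdown curves")
    ref = float(np.max(erms.ion_intensities[precursor_mz]))
    if ref <= 0:
        raise ValueError(
            f"precursor intensity is zero everywhere for {erms.compound_id!r}; "
            "normalization undefined"
        )
    curves = {
        mz: intensities / ref for mz, intensities in erms.ion_intensities.items()
    }
    return BreakdownCurveSet(
        compound_id=erms.compound_id,
        precursor_mz=precursor_mz,
        collision_voltages=erms.collision_voltages.copy(),
        yield_curves=curves,
    )


def select_diagnostic_ions(
    curves: BreakdownCurveSet, yield_threshold: float = 0.10
) -> list[tuple[float, float]]:
    """Pick product ions whose maximum yield exceeds the threshold.

    Returns (ion m/z, CV at maximum yield) pairs, sorted by descending
    maximum yield with ties broken by ascending m/z. The precursor itself
    is never returned — it is the reference, not a diagnostic fragment.
    The argmax CV is taken on the acquired discrete grid, no interpolation.
    """
    if not 0 < yield_threshold <= 1:
        raise ValueError("yield_threshold must lie in (0, 1]")
    picked = []
    for mz, curve in curves.yield_curves.items():
        if mz == curves.precursor_mz:
            continue
        peak = float(np.max(curve))
        if peak > yield_threshold:
            cv_opt = float(curves.collision_voltages[int(np.argmax(curve))])
            picked.append((mz, cv_opt, peak))
    picked.sort(key=lambda item: (-item[2], item[0]))
    return [(mz, cv) for mz, cv, _ in picked]
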