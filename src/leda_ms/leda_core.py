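"""Linear-equation deconvolution of co-eluting isomer MRM signals.

Isomers that share every product ion still differ in how efficiently they
form each fragment. With a reference-ion channel Ri (the precursor kept
intact at low CV) and a set of product-ion channels Pi, the measured
abundance ratio of each Pi to Ri in a mixed, chromatographically
unresolved peak is a linear combination of the pure-compound
characteristic ratios:

    (Pi/Ri)_measured = sum_x (Pi/Ri)_x * f_x

where f_x is the fraction of isomer x in the precursor-ion signal.
Stacking one such equation per monitored transition gives a square
(n transitions = n isomers) or overdetermined linear system whose
least-squares solution is the isomer composition. The same solve can be
applied either to integrated peak areas (one composition per peak) or
scan by scan along the chromatogram, which partitions the unresolved Ri
peak into per-isomer reconstructed profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .signal_io import MRMTrace, SampleRecord

#: Condition number above which a coefficient matrix is treated as singular.
COND_LIMIT = 1e8

#: In scan-by-scan mode, scans where Ri falls below this fraction of its
#: in-window maximum are skipped (ratios are undefined near a zero denominator).
RI_FLOOR_FRACTION = 0.01


@dataclass
class RatioTable:
    """Characteristic (Pi/Ri)_x yields of pure isomers, with replicate SDs.

    Rows are transitions (labelled "product_mz/reference_mz"), columns are
    isomers; the layout mirrors how such tables are printed.
    """

    isomer_ids: list[str]
    transition_labels: list[str]
    ratios: np.ndarray
    ratio_sds: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.atleast_2d(np.asarray(self.ratios, dtype=float))
        self.ratio_sds = np.atleast_2d(np.asarray(self.ratio_sds, dtype=float))
        n_rows, n_cols = len(self.transition_labels), len(self.isomer_ids)
        if self.ratios.shape != (n_rows, n_cols):
            raise ValueError(
                f"ratio matrix shape {self.ratios.shape} does not match "
                f"{n_rows} transitions x {n_cols} isomers"
            )
        if self.ratio_sds.shape != self.ratios.shape:
            raise ValueError("ratio_sds shape must match ratios")
        if n_cols < 1:
            raise ValueError("need at least one isomer")
        if np.any(self.ratios < 0):
            raise ValueError("characteristic ratios must be non-negative")

    def column(self, isomer_id: str) -> np.ndarray:
        return self.ratios[:, self.isomer_ids.index(isomer_id)]

    @classmethod
    def from_csv(cls, path) -> "RatioTable":
        """Load from long-format CSV (transition_label, isomer_id, ratio, sd)."""
        frame = pd.read_csv(path, dtype={"transition_label": str, "isomer_id": str})
        labels = list(dict.fromkeys(frame["transition_label"]))
        isomers = list(dict.fromkeys(frame["isomer_id"]))
        ratios = frame.pivot(
            index="transition_label", columns="isomer_id", values="ratio"
        ).loc[labels, isomers]
        sds = frame.pivot(
            index="transition_label", columns="isomer_id", values="sd"
        ).loc[labels, isomers]
        return cls(isomers, labels, ratios.to_numpy(float), sds.to_numpy(float))

    def to_csv(self, path):
        rows = [
            {
                "transition_label": label,
                "isomer_id": isomer,
                "ratio": self.ratios[i, j],
                "sd": self.ratio_sds[i, j],
            }
            for i, label in enumerate(self.transition_labels)
            for j, isomer in enumerate(self.isomer_ids)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


@dataclass
class MeasuredRatios:
    """Pi/Ri abundance ratios measured in one sample."""

    transition_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transition_labels),):
            raise ValueError("values length must match transition_labels")


@dataclass
class DeconvolutionResult:
    """Isomer composition of an unresolved MS/MS signal."""

    fractions: dict[str, float]
    raw_solution: np.ndarray
    residual_norm: float
    mode: str = "area"


@dataclass
class ReconstructedProfiles:
    """Per-isomer partition of the Ri chromatographic profile."""

    times: np.ndarray
    per_isomer_ri: dict[str, np.ndarray]
    measured_ri: np.ndarray
    fractions_by_scan: dict[str, np.ndarray] = field(default_factory=dict)

    def area_fractions(self) -> dict[str, float]:
        """Share of the total reconstructed Ri area carried by each isomer."""
        areas = {
            iso: float(np.trapezoid(y, self.times))
            for iso, y in self.per_isomer_ri.items()
        }
        total = sum(areas.values())
        if total <= 0:
            raise ValueError("reconstructed profiles carry no signal")
        return {iso: a / total for iso, a in areas.items()}


def builtin_ratio_table(name: str) -> RatioTable:
    """Load one of the characteristic-ratio tables shipped with the package.

    Available names: 'fra76_gde5', 'elf94_elf96'.
    """
    path = Path(__file__).parent / "fixtures" / f"table4_{name}.csv"
    if not path.exists():
        raise KeyError(f"no built-in ratio table named {name!r}")
    return RatioTable.from_csv(path)


def integrate_peak(trace: MRMTrace, window: tuple[float, float]) -> float:
    """Trapezoidal area (counts·min) of a trace restricted to a time window.

    Points inside the window are used together with linearly interpolated
    intensities at the window edges, so the area varies continuously with
    the window bounds.
    """
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ValueError(f"empty window ({start}, {end})")
    t, y = trace.times, trace.intensities
    if end <= t[0] or start >= t[-1]:
        raise ValueError(
            f"window ({start}, {end}) does not overlap trace domain "
            f"[{t[0]}, {t[-1]}]"
        )
    lo, hi = max(start, t[0]), min(end, t[-1])
    inside = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inside], [hi]))
    yy = np.concatenate(
        ([np.interp(lo, t, y)], y[inside], [np.interp(hi, t, y)])
    )
    return float(np.trapezoid(yy, tt))


def compute_characteristic_ratios(
    pure_samples: SampleRecord | list[SampleRecord],
    window: tuple[float, float],
    isomer_id: str,
    ri_label: str | None = None,
) -> RatioTable:
    """Estimate one isomer's (Pi/Ri)_x column from pure-compound injections.

    Each record contributes one area ratio per Pi transition; with several
    replicate records the column is the replicate mean and the SD column is
    the replicate standard deviation (ddof=1), otherwise SDs are zero.
    """
    if isinstance(pure_samples, SampleRecord):
        pure_samples = [pure_samples]
    if not pure_samples:
        raise ValueError("need at least one pure-compound record")

    per_label: dict[str, list[float]] = {}
    for rec in pure_samples:
        ri_trace = (
            rec.traces[ri_label] if ri_label is not None else rec.trace_by_role("Ri")
        )
        ri_area = integrate_peak(ri_trace, window)
        if ri_area <= 0:
            raise ValueError(
                f"sample {rec.sample_id!r}: Ri peak area is zero in window {window}"
            )
        ref_mz = ri_trace.transition.precursor_mz
        for tid, trace in sorted(rec.traces.items()):
            if trace.transition.role != "Pi":
                continue
            label = f"{trace.transition.product_mz:g}/{ref_mz:g}"
            per_label.setdefault(label, []).append(
                integrate_peak(trace, window) / ri_area
            )
    if not per_label:
        raise ValueError("no Pi transitions found in the supplied records")

    n_rep = len(pure_samples)
    for label, vals in per_label.items():
        if len(vals) != n_rep:
            raise ValueError(f"transition {label!r} missing from some replicates")

    labels = sorted(per_label, key=lambda s: -float(s.split("/")[0]))
    means = np.array([[np.mean(per_label[lb])] for lb in labels])
    sds = np.array(
        [[np.std(per_label[lb], ddof=1) if n_rep > 1 else 0.0] for lb in labels]
    )
    return RatioTable([isomer_id], labels, means, sds)


def _check_rank(matrix: np.ndarray, isomer_ids: list[str]) -> None:
    if np.linalg.cond(matrix) > COND_LIMIT:
        worst, worst_pair = -1.0, (isomer_ids[0], isomer_ids[-1])
        for i in range(matrix.shape[1]):
            for j in range(i + 1, matrix.shape[1]):
                a, b = matrix[:, i], matrix[:, j]
                denom = np.linalg.norm(a) * np.linalg.norm(b)
                cos = abs(a @ b) / denom if denom > 0 else 1.0
                if cos > worst:
                    worst, worst_pair = cos, (isomer_ids[i], isomer_ids[j])
        raise np.linalg.LinAlgError(
            "coefficient matrix is rank-deficient: the characteristic ratios of "
            f"{worst_pair[0]!r} and {worst_pair[1]!r} are not distinguishable on "
            "the chosen transitions"
        )


def assemble_leda_matrix(
    table: RatioTable, transitions: list[str] | None = None
) -> np.ndarray:
    """Build the coefficient matrix (rows = transitions, columns = isomers).

    ``transitions=None`` uses every transition in the table (the
    overdetermined, all-ion variant); a two-row subset of a binary pair
    gives the minimal square system. The system must be square or
    overdetermined and numerically full rank.
    """
    if transitions is None:
        transitions = list(table.transition_labels)
    unknown = [t for t in transitions if t not in table.transition_labels]
    if unknown:
        raise KeyError(f"transitions not in the ratio table: {unknown}")
    rows = [table.transition_labels.index(t) for t in transitions]
    matrix = table.ratios[rows, :]
    if matrix.shape[0] < matrix.shape[1]:
        raise ValueError(
            f"under-determined system: {matrix.shape[0]} equations for "
            f"{matrix.shape[1]} isomers"
        )
    _check_rank(matrix, table.isomer_ids)
    return matrix


def deconvolve(
    measured: MeasuredRatios,
    matrix: np.ndarray,
    isomer_ids: list[str],
    *,
    nonneg: bool = True,
    closure: bool = False,
) -> DeconvolutionResult:
    """Solve the linear system for the isomer fractions.

    Square full-rank systems are solved exactly; overdetermined ones in the
    least-squares sense. ``nonneg`` constrains the solution to be
    physically meaningful (no negative abundances, via NNLS); ``closure``
    rescales the fractions to sum to one. Reported fractions are clipped
    to [0, 1]; ``raw_solution`` keeps the unclipped solve and
    ``residual_norm`` the Euclidean misfit — a residual well above the
    measurement noise flags an unknown co-eluting component.
    """
    b = measured.values
    if np.any(b < 0):
        raise ValueError("measured ratios must be non-negative")
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] != len(b):
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but {len(b)} measured ratios"
        )
    if matrix.shape[1] != len(isomer_ids):
        raise ValueError("matrix column count must match isomer_ids")
    _check_rank(matrix, isomer_ids)

    if nonneg:
        solution, _ = nnls(matrix, b)
    else:
        solution, *_ = np.linalg.lstsq(matrix, b, rcond=None)
    residual = float(np.linalg.norm(b - matrix @ solution))

    fractions = solution.copy()
    if closure:
        total = fractions.sum()
        if total > 0:
            fractions = fractions / total
    fractions = np.clip(fractions, 0.0, 1.0)
    return DeconvolutionResult(
        fractions=dict(zip(isomer_ids, fractions.tolist())),
        raw_solution=solution,
        residual_norm=residual,
        mode="area",
    )


def _measured_from_areas(
    sample: SampleRecord,
    transition_labels: list[str],
    window: tuple[float, float],
) -> MeasuredRatios:
    ri_trace = sample.trace_by_role("Ri")
    ri_area = integrate_peak(ri_trace, window)
    if ri_area <= 0:
        raise ValueError(f"sample {sample.sample_id!r}: zero Ri area in {window}")
    ref_mz = ri_trace.transition.precursor_mz
    by_label = {
        f"{t.transition.product_mz:g}/{ref_mz:g}": t
        for t in sample.traces.values()
        if t.transition.role == "Pi"
    }
    values = []
    for label in transition_labels:
        if label not in by_label:
            raise KeyError(f"sample {sample.sample_id!r} lacks transition {label!r}")
        values.append(integrate_peak(by_label[label], window) / ri_area)
    return MeasuredRatios(transition_labels, np.asarray(values))


def peak_purity(
    sample: SampleRecord,
    matrix: np.ndarray,
    table: RatioTable,
    window: tuple[float, float],
    transitions: list[str] | None = None,
    *,
    nonneg: bool = True,
    closure: bool = False,
) -> DeconvolutionResult:
    """Composition of the unresolved peak from integrated channel areas."""
    labels = transitions if transitions is not None else list(table.transition_labels)
    measured = _measured_from_areas(sample, labels, window)
    result = deconvolve(
        measured, matrix, table.isomer_ids, nonneg=nonneg, closure=closure
    )
    result.mode = "area"
    return result


def deconvolve_scanwise(
    sample: SampleRecord,
    matrix: np.ndarray,
    table: RatioTable,
    window: tuple[float, float],
    transitions: list[str] | None = None,
    *,
    nonneg: bool = True,
    ri_floor_fraction: float = RI_FLOOR_FRACTION,
) -> ReconstructedProfiles:
    """Repeat the deconvolution at every scan, partitioning the Ri profile.

    All Pi traces are linearly interpolated onto the Ri time grid (MRM
    channels are acquired interleaved, so their timestamps differ). At
    each scan where Ri exceeds the floor, the instantaneous Pi/Ri ratios
    are deconvolved with closure on and each isomer receives its share of
    Ri(t); below-floor scans contribute zero to every isomer.
    """
    labels = transitions if transitions is not None else list(table.transition_labels)
    ri_trace = sample.trace_by_role("Ri")
    ref_mz = ri_trace.transition.precursor_mz
    by_label = {
        f"{t.transition.product_mz:g}/{ref_mz:g}": t
        for t in sample.traces.values()
        if t.transition.role == "Pi"
    }
    missing = [lb for lb in labels if lb not in by_label]
    if missing:
        raise KeyError(f"sample {sample.sample_id!r} lacks transitions {missing}")

    start, end = window
    t_lo = max(start, ri_trace.times[0], *(by_label[lb].times[0] for lb in labels))
    t_hi = min(end, ri_trace.times[-1], *(by_label[lb].times[-1] for lb in labels))
    mask = (ri_trace.times >= t_lo) & (ri_trace.times <= t_hi)
    if mask.sum() < 2:
        raise ValueError(f"traces do not overlap within window {window}")
    times = ri_trace.times[mask]
    ri = ri_trace.intensities[mask]
    pi = np.vstack(
        [
            np.interp(times, by_label[lb].times, by_label[lb].intensities)
            for lb in labels
        ]
    )

    floor = ri_floor_fraction * float(ri.max())
    n_iso = len(table.isomer_ids)
    frac_scan = np.zeros((n_iso, len(times)))
    for j in np.flatnonzero(ri > floor):
        measured = MeasuredRatios(labels, pi[:, j] / ri[j])
        res = deconvolve(
            measured, matrix, table.isomer_ids, nonneg=nonneg, closure=True
        )
        frac_scan[:, j] = [res.fractions[iso] for iso in table.isomer_ids]

    profiles = {
        iso: frac_scan[i] * ri for i, iso in enumerate(table.isomer_ids)
    }
    return ReconstructedProfiles(
        times=times,
        per_isomer_ri=profiles,
        measured_ri=ri,
        fractions_by_scan={
            iso: frac_scan[i] for i, iso in enumerate(table.isomer_ids)
        },
    )
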