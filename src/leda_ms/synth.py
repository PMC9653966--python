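"""Seeded synthetic MRM / ERMS data with the structure the analysis assumes.

Chromatographic peaks are Gaussian; the default width derives from the
low plate count of a short, fast column (sigma = t_R / sqrt(N) with
N = 5000). Channel areas carry multiplicative log-normal noise of
configurable coefficient of variation (mean-unbiased), emulating
injection-to-injection and ionization variability; the default CV of 2%
reproduces the replicate scatter of characteristic-ratio measurements.
All isomers co-elute exactly, so the reference-ion peak is unresolved by
construction and only the deconvolution can apportion it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leda_core import RatioTable, builtin_ratio_table
from .signal_io import MRMTrace, SampleRecord, TransitionDescriptor, ERMSTable

PLATE_COUNT = 5000.0


def _default_table() -> RatioTable:
    return builtin_ratio_table("elf94_elf96")


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    ``ri_base_area`` is the reference-ion peak area (counts·min) produced
    by the 100 ng/mL top calibration level; areas scale linearly with
    concentration below that.
    """

    seed: int = 0
    retention_time: float = 1.8                 # minutes
    peak_sigma: float | None = None             # minutes; default t_R/sqrt(N)
    noise_cv: float = 0.02                      # fractional CV of channel areas
    ri_base_area: float = 1.0e6                 # counts·min at 100 ng/mL
    is_area: float = 5.0e5                      # counts·min
    ratio_table: RatioTable = field(default_factory=_default_table)
    run_time: float = 3.6                       # minutes of acquisition
    cycle_time: float = 0.005                   # minutes between scans per channel
    dwell_offset: float = 25e-3 / 60.0          # channel time stagger (25 ms)

    def __post_init__(self) -> None:
        if self.peak_sigma is None:
            self.peak_sigma = self.retention_time / np.sqrt(PLATE_COUNT)
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-unbiased multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def _gaussian_trace(
    config: SynthConfig,
    descriptor: TransitionDescriptor,
    area: float,
    sample_id: str,
    channel_index: int,
) -> MRMTrace:
    offset = channel_index * config.dwell_offset
    times = np.arange(offset, config.run_time, config.cycle_time)
    sigma = config.peak_sigma
    intensities = (
        area
        / (sigma * np.sqrt(2 * np.pi))
        * np.exp(-0.5 * ((times - config.retention_time) / sigma) ** 2)
    )
    return MRMTrace(descriptor, times, intensities, sample_id)


def _parse_label(label: str) -> tuple[float, float]:
    product, reference = label.split("/")
    return float(product), float(reference)


def _descriptors(table: RatioTable) -> tuple[TransitionDescriptor, list[TransitionDescriptor], TransitionDescriptor]:
    precursor = _parse_label(table.transition_labels[0])[1]
    ri = TransitionDescriptor("Ri", precursor, precursor, 10.0, "Ri", "Ri")
    pis = []
    for label in table.transition_labels:
        product, _ = _parse_label(label)
        pis.append(
            TransitionDescriptor(f"Pi_{product:g}", precursor, product, 25.0, "Pi", label)
        )
    is_desc = TransitionDescriptor("IS", 455.0, 165.0, 30.0, "IS", "IS")
    return ri, pis, is_desc


def _sample_from_areas(
    config: SynthConfig,
    sample_id: str,
    ri_area: float,
    pi_areas: np.ndarray,
    rng: np.random.Generator,
    incubation_time: float | None = None,
    nominal_composition: dict[str, float] | None = None,
) -> SampleRecord:
    ri_desc, pi_descs, is_desc = _descriptors(config.ratio_table)
    traces = {}
    noisy_ri = ri_area * _noise_factor(rng, config.noise_cv)
    traces[ri_desc.transition_id] = _gaussian_trace(
        config, ri_desc, noisy_ri, sample_id, 0
    )
    for i, (desc, area) in enumerate(zip(pi_descs, pi_areas), start=1):
        traces[desc.transition_id] = _gaussian_trace(
            config, desc, area * _noise_factor(rng, config.noise_cv), sample_id, i
        )
    traces[is_desc.transition_id] = _gaussian_trace(
        config,
        is_desc,
        config.is_area * _noise_factor(rng, config.noise_cv),
        sample_id,
        len(pi_descs) + 1,
    )
    return SampleRecord(
        sample_id=sample_id,
        traces=traces,
        incubation_time=incubation_time,
        nominal_composition=nominal_composition,
    )


def generate_pure_sample(
    config: SynthConfig,
    isomer_id: str,
    concentration: float,
    sample_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> SampleRecord:
    """One injection of a single pure isomer at the given concentration (ng/mL)."""
    if isomer_id not in config.ratio_table.isomer_ids:
        raise KeyError(f"unknown isomer {isomer_id!r}")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = rng if rng is not None else config.rng()
    ri_area = config.ri_base_area * concentration / 100.0
    pi_areas = config.ratio_table.column(isomer_id) * ri_area
    return _sample_from_areas(
        config,
        sample_id or f"pure_{isomer_id}_{concentration:g}",
        ri_area,
        pi_areas,
        rng,
        nominal_composition={isomer_id: 1.0},
    )


def generate_mixture_sample(
    config: SynthConfig,
    composition: dict[str, float],
    total_concentration: float = 100.0,
    sample_id: str | None = None,
    rng: np.random.Generator | None = None,
    incubation_time: float | None = None,
) -> SampleRecord:
    """Co-eluting mixture; every channel is the composition-weighted sum."""
    fractions = np.array(
        [composition.get(iso, 0.0) for iso in config.ratio_table.isomer_ids]
    )
    unknown = set(composition) - set(config.ratio_table.isomer_ids)
    if unknown:
        raise KeyError(f"unknown isomers in composition: {sorted(unknown)}")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions.sum():.12g}")
    rng = rng if rng is not None else config.rng()
    ri_area = config.ri_base_area * total_concentration / 100.0
    pi_areas = (config.ratio_table.ratios @ fractions) * ri_area
    return _sample_from_areas(
        config,
        sample_id or "mixture",
        ri_area,
        pi_areas,
        rng,
        incubation_time=incubation_time,
        nominal_composition=dict(composition),
    )


def generate_mixture_ladder(
    config: SynthConfig,
    compositions: list[dict[str, float]] | None = None,
    total_concentration: float = 100.0,
    replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """The five-level standard-mixture ladder (90/10 ... 10/90 by default)."""
    iso_a, iso_b = config.ratio_table.isomer_ids[:2]
    if compositions is None:
        compositions = [
            {iso_a: a, iso_b: round(1.0 - a, 10)}
            for a in (0.90, 0.75, 0.50, 0.25, 0.10)
        ]
    rng = rng if rng is not None else config.rng()
    records = []
    for level, comp in enumerate(compositions, start=1):
        for rep in range(1, replicates + 1):
            records.append(
                generate_mixture_sample(
                    config,
                    comp,
                    total_concentration,
                    sample_id=f"mix{level}_rep{rep}",
                    rng=rng,
                )
            )
    return records


def generate_degradation_series(
    config: SynthConfig,
    composition: dict[str, float],
    k_map: dict[str, float],
    times: list[float] | None = None,
    replicates: int = 3,
    total_concentration: float = 55.0,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Incubation series: each isomer's concentration decays as exp(-|k|·t).

    ``times`` defaults to the standard 0/30/60/120-min incubation design;
    it must include 0 so the undegraded composition is observed.
    ``total_concentration`` (ng/mL) sits mid-calibration, as plasma-spike
    levels do.
    """
    if times is None:
        times = [0.0, 30.0, 60.0, 120.0]
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise ValueError("incubation times must be non-negative")
    if 0.0 not in times:
        raise ValueError("incubation times must include 0")
    rng = rng if rng is not None else config.rng()
    isomers = config.ratio_table.isomer_ids
    records = []
    for t in times:
        conc = {
            iso: composition.get(iso, 0.0)
            * total_concentration
            * np.exp(-abs(k_map.get(iso, 0.0)) * t)
            for iso in isomers
        }
        total_t = sum(conc.values())
        comp_t = {iso: c / total_t for iso, c in conc.items()}
        for rep in range(1, replicates + 1):
            rec = generate_mixture_sample(
                config,
                comp_t,
                total_concentration=total_t,
                sample_id=f"t{t:g}_rep{rep}",
                rng=rng,
                incubation_time=t,
            )
            rec.metadata["true_concentrations_ng_ml"] = conc
            records.append(rec)
    return records


def generate_concentration_series(
    config: SynthConfig,
    k: float,
    times: list[float] | None = None,
    replicates: int = 3,
    c0: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct concentration readout (µM) of a first-order decay with noise.

    Returns pooled (times, concentrations) vectors, one entry per
    replicate per time point — the exact input shape the kinetics fit
    expects. ``c0`` defaults to the 1 µM plasma spike level.
    """
    if times is None:
        times = [0.0, 30.0, 60.0, 120.0]
    rng = rng if rng is not None else config.rng()
    t_out, c_out = [], []
    for t in times:
        for _ in range(replicates):
            t_out.append(float(t))
            c_out.append(
                c0 * np.exp(-abs(k) * t) * _noise_factor(rng, config.noise_cv)
            )
    return np.asarray(t_out), np.asarray(c_out)


def generate_erms_table(
    config: SynthConfig,
    yield_profiles: dict[float, tuple[float, float, float]],
    precursor_mz: float,
    compound_id: str = "synthetic",
    collision_voltages: np.ndarray | None = None,
    precursor_scale: float = 1.0e5,
) -> ERMSTable:
    """CV sweep with known fragment-yield maxima.

    ``yield_profiles`` maps fragment m/z to (max_yield, cv_of_max, width);
    each fragment follows a Gaussian-in-CV profile peaking at exactly
    max_yield relative to the precursor's maximum intensity, while the
    precursor survival decays exponentially from the lowest CV. Feeding
    the result to the breakdown-curve builder recovers the stated maxima.
    """
    cvs = (
        np.arange(5.0, 51.0, 5.0)
        if collision_voltages is None
        else np.asarray(collision_voltages, dtype=float)
    )
    if not np.all(np.diff(cvs) > 0):
        raise ValueError("collision voltages must be ascending")
    if cvs[0] < 5.0 or cvs[-1] > 50.0:
        raise ValueError("collision voltages must lie within 5-50 V")
    ions: dict[float, np.ndarray] = {
        float(precursor_mz): precursor_scale * np.exp(-(cvs - cvs[0]) / 15.0)
    }
    for mz, (max_yield, cv_of_max, width) in yield_profiles.items():
        if width <= 0:
            raise ValueError(f"ion {mz}: width must be positive")
        ions[float(mz)] = (
            max_yield
            * precursor_scale
            * np.exp(-0.5 * ((cvs - cv_of_max) / width) ** 2)
        )
    return ERMSTable(compound_id, cvs, ions)
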