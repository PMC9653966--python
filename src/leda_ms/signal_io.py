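"""Data model and I/O for MRM chromatograms and ERMS tables.

The canonical exchange format is a tidy CSV with one row per acquired
data point (columns: sample_id, transition_id, precursor_mz, product_mz,
collision_voltage, role, time_min, intensity). Vendor raw files are out
of scope; mzML files containing SRM chromatograms can also be read (a
lightweight reader covering only the chromatogram entries of the format).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIDY_COLUMNS = [
    "sample_id",
    "transition_id",
    "precursor_mz",
    "product_mz",
    "collision_voltage",
    "role",
    "time_min",
    "intensity",
]

VALID_ROLES = {"Ri", "Pi", "IS"}


class ValidationError(ValueError):
    """An input violates a structural invariant (no silent coercion)."""


class ParseError(ValueError):
    """A file does not follow the tidy dialect."""


@dataclass(frozen=True)
class TransitionDescriptor:
    """One MRM transition: precursor -> product at a fixed collision voltage.

    ``role`` distinguishes the reference-ion channel (Ri, precursor kept
    intact at low CV, so product m/z equals precursor m/z), product-ion
    channels (Pi) and the internal standard (IS).
    """

    transition_id: str
    precursor_mz: float
    product_mz: float
    collision_voltage: float
    role: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValidationError(
                f"transition {self.transition_id!r}: m/z values must be positive"
            )
        if self.role not in VALID_ROLES:
            raise ValidationError(
                f"transition {self.transition_id!r}: role {self.role!r} "
                f"not in {sorted(VALID_ROLES)}"
            )
        if self.role == "Pi" and self.product_mz > self.precursor_mz:
            raise ValidationError(
                f"transition {self.transition_id!r}: product m/z exceeds precursor m/z"
            )
        if self.role == "Ri" and self.product_mz != self.precursor_mz:
            raise ValidationError(
                f"transition {self.transition_id!r}: an Ri transition must have "
                "product_mz == precursor_mz"
            )


@dataclass
class MRMTrace:
    """Intensity-versus-time series of a single transition in one sample."""

    transition: TransitionDescriptor
    times: np.ndarray
    intensities: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValidationError("a trace needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"times not strictly increasing for transition "
                f"{self.transition.transition_id!r} in sample {self.sample_id!r}"
            )
        if np.any(self.intensities < 0):
            raise ValidationError(
                f"negative intensity in transition {self.transition.transition_id!r}"
            )


@dataclass
class SampleRecord:
    """All MRM traces acquired for one injection, keyed by transition id."""

    sample_id: str
    traces: dict[str, MRMTrace]
    incubation_time: float | None = None
    nominal_composition: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, trace in self.traces.items():
            if trace.sample_id != self.sample_id:
                raise ValidationError(
                    f"trace {tid!r} carries sample_id {trace.sample_id!r}, "
                    f"record is {self.sample_id!r}"
                )
        if self.nominal_composition is not None:
            for isomer, frac in self.nominal_composition.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValidationError(
                        f"nominal fraction for {isomer!r} outside [0, 1]: {frac}"
                    )

    def trace_by_role(self, role: str) -> MRMTrace:
        """Return the unique trace with the given role ('Ri' or 'IS')."""
        matches = [t for t in self.traces.values() if t.transition.role == role]
        if len(matches) != 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: expected exactly one {role} trace, "
                f"found {len(matches)}"
            )
        return matches[0]


@dataclass
class ERMSTable:
    """Scan-averaged product-ion intensities over a stepped CV range."""

    compound_id: str
    collision_voltages: np.ndarray
    ion_intensities: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        self.collision_voltages = np.asarray(self.collision_voltages, dtype=float)
        if not np.all(np.diff(self.collision_voltages) > 0):
            raise ValidationError("collision voltages must be ascending")
        n = len(self.collision_voltages)
        clean = {}
        for mz, vec in self.ion_intensities.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ValidationError(
                    f"ion {mz}: expected {n} intensities, got {vec.shape}"
                )
            if np.any(vec < 0):
                raise ValidationError(f"ion {mz}: negative intensity")
            clean[float(mz)] = vec
        self.ion_intensities = clean


def _sample_from_group(sample_id: str, group: pd.DataFrame) -> SampleRecord:
    traces: dict[str, MRMTrace] = {}
    extra_cols = [c for c in group.columns if c not in TIDY_COLUMNS]
    for tid, tgroup in group.groupby("transition_id", sort=True):
        tgroup = tgroup.sort_values("time_min")
        if tgroup["time_min"].duplicated().any():
            raise ValidationError(
                f"duplicate time points for transition {tid!r} in sample "
                f"{sample_id!r} (ambiguous rows are not averaged)"
            )
        first = tgroup.iloc[0]
        desc = TransitionDescriptor(
            transition_id=str(tid),
            precursor_mz=float(first["precursor_mz"]),
            product_mz=float(first["product_mz"]),
            collision_voltage=float(first["collision_voltage"]),
            role=str(first["role"]),
            label=str(first.get("label", "")) if "label" in tgroup.columns else "",
        )
        traces[str(tid)] = MRMTrace(
            transition=desc,
            times=tgroup["time_min"].to_numpy(float),
            intensities=tgroup["intensity"].to_numpy(float),
            sample_id=str(sample_id),
        )
    metadata = {}
    incubation = None
    nominal = None
    for col in extra_cols:
        value = group[col].iloc[0]
        if col == "incubation_time_min":
            if pd.notna(value):
                incubation = float(value)
        elif col == "nominal_composition":
            if pd.notna(value) and str(value):
                nominal = _parse_composition(str(value))
        elif col != "label":
            metadata[col] = value
    return SampleRecord(
        sample_id=str(sample_id),
        traces=traces,
        incubation_time=incubation,
        nominal_composition=nominal,
        metadata=metadata,
    )


def _parse_composition(text: str) -> dict[str, float]:
    pairs = [item.split("=") for item in text.split(";") if item]
    return {name: float(frac) for name, frac in pairs}


def _format_composition(composition: dict[str, float]) -> str:
    return ";".join(f"{name}={frac:.9g}" for name, frac in composition.items())


def read_mrm_csv(path) -> list[SampleRecord]:
    """Read a tidy MRM CSV into one SampleRecord per distinct sample_id."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in TIDY_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ("precursor_mz", "product_mz", "collision_voltage", "time_min", "intensity"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            line = int(frame.index[bad | frame[col].isna()][0]) + 2  # header is line 1
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        frame[col] = coerced
    return [
        _sample_from_group(sid, group)
        for sid, group in frame.groupby("sample_id", sort=True)
    ]


def write_mrm_csv(records, path):
    """Write SampleRecords to the tidy CSV dialect; returns the path.

    Round-trips through ``read_mrm_csv`` losslessly to 9 significant digits.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record set")
    rows = []
    for rec in records:
        for tid in sorted(rec.traces):
            trace = rec.traces[tid]
            d = trace.transition
            for t, y in zip(trace.times, trace.intensities):
                row = {
                    "sample_id": rec.sample_id,
                    "transition_id": tid,
                    "precursor_mz": d.precursor_mz,
                    "product_mz": d.product_mz,
                    "collision_voltage": d.collision_voltage,
                    "role": d.role,
                    "time_min": t,
                    "intensity": y,
                    "label": d.label,
                }
                if rec.incubation_time is not None:
                    row["incubation_time_min"] = rec.incubation_time
                if rec.nominal_composition is not None:
                    row["nominal_composition"] = _format_composition(
                        rec.nominal_composition
                    )
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_erms_csv(path) -> list[ERMSTable]:
    """Read ERMS tables from CSV (compound_id, collision_voltage, ion_mz, intensity)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = ["compound_id", "collision_voltage", "ion_mz", "intensity"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    tables = []
    for cid, group in frame.groupby("compound_id", sort=True):
        cvs = np.sort(group["collision_voltage"].unique())
        ions = {}
        for mz, igroup in group.groupby("ion_mz"):
            igroup = igroup.set_index("collision_voltage").reindex(cvs)
            ions[float(mz)] = igroup["intensity"].fillna(0.0).to_numpy(float)
        tables.append(ERMSTable(str(cid), cvs, ions))
    return tables


def write_erms_csv(tables, path):
    rows = []
    for table in tables:
        for mz in sorted(table.ion_intensities):
            for cv, y in zip(table.collision_voltages, table.ion_intensities[mz]):
                rows.append(
                    {
                        "compound_id": table.compound_id,
                        "collision_voltage": cv,
                        "ion_mz": mz,
                        "intensity": y,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# -- mzML (read-only, SRM chromatogram entries) ------------------------------
#
# Only the chromatogram subtree of mzML is consumed: binary data arrays
# (64/32-bit float, uncompressed or zlib) plus the precursor/product
# isolation-window and collision-energy cvParams. Spectra are ignored.

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_ACC_TIME_ARRAY = "MS:1000595"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_ISOLATION_TARGET = "MS:1000827"
_ACC_COLLISION_ENERGY = "MS:1000045"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.findall(f"{{{_MZML_NS}}}cvParam")
    }


def _decode_binary_array(array_element) -> tuple[str | None, np.ndarray]:
    import base64
    import zlib

    params = _cv_params(array_element)
    kind = None
    in_seconds = False
    if _ACC_TIME_ARRAY in params:
        kind = "time"
        for cv in array_element.findall(f"{{{_MZML_NS}}}cvParam"):
            if cv.get("accession") == _ACC_TIME_ARRAY:
                in_seconds = cv.get("unitName", "") == "second"
    elif _ACC_INTENSITY_ARRAY in params:
        kind = "intensity"
    dtype = "<f4" if _ACC_FLOAT32 in params else "<f8"
    binary = array_element.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode((binary.text or "").encode())
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    return kind, values / 60.0 if in_seconds else values


def _isolation_target(chrom_element, tag: str) -> float | None:
    block = chrom_element.find(f"{{{_MZML_NS}}}{tag}")
    if block is None:
        return None
    iso = block.find(f"{{{_MZML_NS}}}isolationWindow")
    if iso is None:
        return None
    value = _cv_params(iso).get(_ACC_ISOLATION_TARGET)
    return float(value) if value not in (None, "") else None


def _collision_energy(chrom_element) -> float:
    block = chrom_element.find(f"{{{_MZML_NS}}}precursor")
    if block is None:
        return 0.0
    activation = block.find(f"{{{_MZML_NS}}}activation")
    if activation is None:
        return 0.0
    value = _cv_params(activation).get(_ACC_COLLISION_ENERGY)
    try:
        return float(value)
    except (TypeError, ValueError):
        return 0.0


def read_mzml_chromatograms(path) -> list[SampleRecord]:
    """Read SRM/MRM chromatograms from an mzML file.

    Each chromatogram entry with precursor and product isolation windows
    becomes one MRMTrace (TIC/other chromatograms are skipped). Files
    without any such entry — e.g. MS1-only acquisitions — raise a
    "no MRM content" error. Time arrays declared in seconds are converted
    to minutes.
    """
    from lxml import etree

    traces: dict[str, MRMTrace] = {}
    sample_id = str(path)
    for _, chrom in etree.iterparse(
        str(path), events=("end",), tag=f"{{{_MZML_NS}}}chromatogram"
    ):
        cid = chrom.get("id", "")
        prec = _isolation_target(chrom, "precursor")
        prod = _isolation_target(chrom, "product")
        if prec is not None and prod is not None:
            times = intensities = None
            for array_element in chrom.iter(f"{{{_MZML_NS}}}binaryDataArray"):
                kind, values = _decode_binary_array(array_element)
                if kind == "time":
                    times = values
                elif kind == "intensity":
                    intensities = values
            if times is not None and intensities is not None:
                role = "Ri" if prec == prod else "Pi"
                desc = TransitionDescriptor(
                    transition_id=cid or f"{prec:g}->{prod:g}",
                    precursor_mz=prec,
                    product_mz=prod,
                    collision_voltage=_collision_energy(chrom),
                    role=role,
                )
                traces[desc.transition_id] = MRMTrace(
                    transition=desc,
                    times=times,
                    intensities=intensities,
                    sample_id=sample_id,
                )
        chrom.clear()
    if not traces:
        raise ParseError(f"{path}: no MRM content (no SRM chromatogram entries)")
    return [SampleRecord(sample_id=sample_id, traces=traces)]
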