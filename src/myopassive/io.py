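"""Canonical measurement containers and file formats.

The atom of every analysis is one (specimen, sarcomere length, nominal
stress) observation.  The canonical on-disk form is a UTF-8 CSV with a
header row of exactly::

    specimen_id,preparation,fibre_type,sarcomere_length_um,nominal_stress_kpa

preceded by ``# key: value`` comment lines carrying metadata (units are
always recorded and checked: lengths in μm, stresses in kPa; files
declaring other units are rejected on load).  Spreadsheet (xlsx) input
is supported through a user-supplied column map translating sheet
columns to the canonical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, LoadError

__all__ = [
    "MeasurementRecord",
    "Dataset",
    "CANONICAL_COLUMNS",
    "read_measurements",
    "write_measurements",
    "records_to_frame",
    "select_records",
]

PREPARATIONS = ("fibre", "bundle")
FIBRE_TYPES = ("fast", "slow", "mixed", "unknown")

CANONICAL_COLUMNS = [
    "specimen_id",
    "preparation",
    "fibre_type",
    "sarcomere_length_um",
    "nominal_stress_kpa",
]

_CANONICAL_UNITS = {"length_unit": "um", "stress_unit": "kPa"}


@dataclass(frozen=True)
class MeasurementRecord:
    """One passive-stretch observation on a fibre or bundle."""

    specimen_id: str
    preparation: str
    fibre_type: str
    sarcomere_length: float  # μm
    nominal_stress: float  # kPa

    def __post_init__(self):
        if self.preparation not in PREPARATIONS:
            raise DomainError(
                f"preparation must be one of {PREPARATIONS}, got {self.preparation!r}")
        if self.fibre_type not in FIBRE_TYPES:
            raise DomainError(
                f"fibre_type must be one of {FIBRE_TYPES}, got {self.fibre_type!r}")
        if not (np.isfinite(self.sarcomere_length) and self.sarcomere_length > 0):
            raise DomainError(
                f"sarcomere_length must be > 0, got {self.sarcomere_length}")
        if not (np.isfinite(self.nominal_stress) and self.nominal_stress >= 0):
            raise DomainError(
                f"nominal_stress must be >= 0, got {self.nominal_stress}")


@dataclass
class Dataset:
    """A list of measurement records plus free-form metadata."""

    records: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(_CANONICAL_UNITS)
        merged.update(self.metadata)
        for key, expected in _CANONICAL_UNITS.items():
            got = str(merged[key])
            if got not in (expected, "μm" if expected == "um" else expected):
                raise LoadError(
                    f"unsupported {key} {got!r}: this package stores lengths "
                    f"in μm and stresses in kPa only")
        self.metadata = merged

    def __len__(self):
        return len(self.records)


def records_to_frame(records) -> pd.DataFrame:
    """Canonical DataFrame view of a record sequence."""
    return pd.DataFrame(
        [(r.specimen_id, r.preparation, r.fibre_type,
          r.sarcomere_length, r.nominal_stress) for r in records],
        columns=CANONICAL_COLUMNS,
    )


def select_records(records, group: str):
    """Filter records by group label.

    Groups: ``fast`` / ``slow`` (fibres of that type), ``fibre`` /
    ``bundle`` (by preparation), ``pooled`` (all fibres).
    """
    if group in ("fast", "slow"):
        return [r for r in records
                if r.preparation == "fibre" and r.fibre_type == group]
    if group in ("fibre", "bundle"):
        return [r for r in records if r.preparation == group]
    if group == "pooled":
        return [r for r in records if r.preparation == "fibre"]
    if group == "all":
        return list(records)
    raise DomainError(f"unknown group {group!r}")


def _read_metadata_lines(path):
    meta = {}
    n_comment = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n_comment


def _frame_to_dataset(frame: pd.DataFrame, metadata: dict, line_of) -> Dataset:
    """Validate a canonical-column frame row by row; collect line errors."""
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise LoadError(f"missing required columns: {missing}")
    records = []
    errors = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = line_of(i)
        try:
            length = float(getattr(row, "sarcomere_length_um"))
            stress = float(getattr(row, "nominal_stress_kpa"))
        except (TypeError, ValueError):
            errors.append((line, "non-numeric length or stress"))
            continue
        try:
            records.append(MeasurementRecord(
                specimen_id=str(getattr(row, "specimen_id")),
                preparation=str(getattr(row, "preparation")),
                fibre_type=str(getattr(row, "fibre_type")),
                sarcomere_length=length,
                nominal_stress=stress,
            ))
        except DomainError as exc:
            errors.append((line, str(exc)))
    if errors:
        listing = "; ".join(f"line {ln}: {msg}" for ln, msg in errors)
        raise LoadError(f"{len(errors)} invalid row(s): {listing}", errors)
    return Dataset(records=records, metadata=metadata)


def read_measurements(path, format: str | None = None,
                      column_map: dict | None = None,
                      sheet=0) -> Dataset:
    """Load measurements from a canonical CSV or a mapped spreadsheet.

    Parameters
    ----------
    path : str or Path
    format : "csv" or "xlsx"; inferred from the suffix when None.
    column_map : for xlsx input, a mapping from sheet column names to the
        canonical column names (values must cover all canonical columns).
    sheet : sheet name or index for xlsx input.
    """
    path = str(path)
    if format is None:
        format = "xlsx" if path.lower().endswith((".xlsx", ".xls")) else "csv"
    if format == "csv":
        metadata, n_comment = _read_metadata_lines(path)
        try:
            frame = pd.read_csv(path, comment="#", dtype=str)
        except pd.errors.EmptyDataError:
            raise LoadError("file has no header row")
        # data row i sits after the comment block and the header line
        return _frame_to_dataset(frame, metadata, lambda i: n_comment + 2 + i)
    if format == "xlsx":
        frame = pd.read_excel(path, sheet_name=sheet, dtype=object)
        if column_map:
            unknown = [c for c in column_map if c not in frame.columns]
            if unknown:
                raise LoadError(f"column_map refers to absent columns: {unknown}")
            frame = frame.rename(columns=column_map)
        # +2: header row is spreadsheet row 1
        return _frame_to_dataset(frame, {}, lambda i: i + 2)
    raise LoadError(f"unknown format {format!r}")


def write_measurements(dataset: Dataset, path) -> None:
    """Write a dataset as canonical CSV (metadata as leading # comments)."""
    frame = records_to_frame(dataset.records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in dataset.metadata.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)
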