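"""Admission-level EHR records: parsing, validation, and ordering.

The unit of observation is one hospitalization (admission): a patient, an
admission time, the diagnoses made during that stay, and the drugs
prescribed.  Diagnosis and drug codes are opaque, case-sensitive strings —
no ICD hierarchy collapsing is attempted.  Only the relative order of a
patient's admissions is consumed downstream, never absolute time, so the
``admission_time`` field may be an integer order index or an ISO-8601 date.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "AdmissionRecord",
    "RecordSet",
    "SchemaError",
    "RecordValidationError",
    "read_records",
    "write_records",
    "patient_histories",
    "table1_fixture",
]

CSV_COLUMNS = ("hospital_id", "patient_id", "admission_time", "diagnoses", "medicines")
_MULTI_SEP = ";"


class SchemaError(ValueError):
    """A required column or field is missing from the input."""


class RecordValidationError(ValueError):
    """A row violates a record-level invariant (empty diagnoses, duplicates...)."""


def _time_key(t: object) -> tuple[int, object]:
    """Sort key tolerant of mixed integer / string admission times."""
    if isinstance(t, bool):
        raise TypeError("admission_time may not be boolean")
    if isinstance(t, (int, float)):
        return (0, float(t))
    s = str(t)
    try:
        return (0, float(s))
    except ValueError:
        return (1, s)


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalization.

    ``diagnoses`` keeps input order (it feeds the temporal disease sequence);
    ``medicines`` is order-preserving but has set semantics — duplicates are
    rejected at construction.
    """

    hospital_id: str
    patient_id: str
    admission_time: object
    diagnoses: tuple[str, ...]
    medicines: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.hospital_id:
            raise RecordValidationError("hospital_id must be non-empty")
        if not self.patient_id:
            raise RecordValidationError("patient_id must be non-empty")
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        object.__setattr__(self, "medicines", tuple(self.medicines))
        if not self.diagnoses or any(not d for d in self.diagnoses):
            raise RecordValidationError(
                f"admission {self.hospital_id!r}: diagnoses must be a non-empty "
                "sequence of non-empty codes"
            )
        if len(set(self.diagnoses)) != len(self.diagnoses):
            raise RecordValidationError(
                f"admission {self.hospital_id!r}: duplicate diagnosis code"
            )
        if len(set(self.medicines)) != len(self.medicines):
            raise RecordValidationError(
                f"admission {self.hospital_id!r}: duplicate medicine code"
            )

    @property
    def medicine_set(self) -> frozenset[str]:
        return frozenset(self.medicines)

    def sort_key(self) -> tuple:
        return (*_time_key(self.admission_time), self.hospital_id)


@dataclass(frozen=True)
class RecordSet:
    """A validated, deterministically ordered collection of admissions.

    Iteration order is sorted by ``(admission_time, hospital_id)``; the
    hospital-ID tie-break makes every downstream computation reproducible
    when several admissions share a timestamp.
    """

    records: tuple[AdmissionRecord, ...]

    def __init__(self, records: Iterable[AdmissionRecord]) -> None:
        ordered = tuple(sorted(records, key=lambda r: r.sort_key()))
        seen: set[str] = set()
        for r in ordered:
            if r.hospital_id in seen:
                raise RecordValidationError(
                    f"duplicate hospital_id {r.hospital_id!r} in record set"
                )
            seen.add(r.hospital_id)
        object.__setattr__(self, "records", ordered)

    def __iter__(self) -> Iterator[AdmissionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(sorted({r.patient_id for r in self.records}))


def patient_histories(rs: RecordSet) -> dict[str, list[AdmissionRecord]]:
    """Partition a record set into per-patient, time-ordered histories."""
    out: dict[str, list[AdmissionRecord]] = {}
    for rec in rs:  # rs iterates in (time, hospital_id) order already
        out.setdefault(rec.patient_id, []).append(rec)
    return out


def _split_multi(cell: str) -> list[str]:
    return [p.strip() for p in cell.split(_MULTI_SEP) if p.strip()]


def read_records(path: str | Path, format: str = "csv") -> RecordSet:
    """Read admissions from CSV or JSON.

    CSV dialect: header ``hospital_id,patient_id,admission_time,diagnoses,
    medicines`` with multi-valued cells ``;``-separated.  JSON: an array of
    objects with the same keys, ``diagnoses``/``medicines`` as arrays.

    Raises
    ------
    SchemaError
        when a required column/field is absent (the message names it).
    RecordValidationError
        when a row violates an invariant (the message carries the row index).
    """
    path = Path(path)
    if format == "csv":
        rows = _read_csv_rows(path)
    elif format == "json":
        rows = _read_json_rows(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")

    records = []
    for idx, row in enumerate(rows):
        try:
            records.append(
                AdmissionRecord(
                    hospital_id=str(row["hospital_id"]),
                    patient_id=str(row["patient_id"]),
                    admission_time=row["admission_time"],
                    diagnoses=tuple(row["diagnoses"]),
                    medicines=tuple(row["medicines"]),
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"row {idx}: {exc}") from exc
    return RecordSet(records)


def _read_csv_rows(path: Path) -> list[dict]:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in CSV_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        rows = []
        for raw in reader:
            rows.append(
                {
                    "hospital_id": raw["hospital_id"],
                    "patient_id": raw["patient_id"],
                    "admission_time": raw["admission_time"],
                    "diagnoses": _split_multi(raw["diagnoses"]),
                    "medicines": _split_multi(raw["medicines"]),
                }
            )
    return rows


def _read_json_rows(path: Path) -> list[dict]:
    with path.open() as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise SchemaError("JSON input must be an array of admission objects")
    rows = []
    for idx, obj in enumerate(data):
        for key in CSV_COLUMNS:
            if key not in obj:
                raise SchemaError(f"object {idx}: missing required field {key!r}")
        rows.append(
            {
                "hospital_id": obj["hospital_id"],
                "patient_id": obj["patient_id"],
                "admission_time": obj["admission_time"],
                "diagnoses": list(obj["diagnoses"]),
                "medicines": list(obj["medicines"]),
            }
        )
    return rows


def write_records(rs: RecordSet, path: str | Path, format: str = "csv") -> None:
    """Write a record set in the same dialect ``read_records`` consumes."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for r in rs:
                writer.writerow(
                    [
                        r.hospital_id,
                        r.patient_id,
                        r.admission_time,
                        _MULTI_SEP.join(r.diagnoses),
                        _MULTI_SEP.join(r.medicines),
                    ]
                )
    elif format == "json":
        payload = [
            {
                "hospital_id": r.hospital_id,
                "patient_id": r.patient_id,
                "admission_time": r.admission_time,
                "diagnoses": list(r.diagnoses),
                "medicines": list(r.medicines),
            }
            for r in rs
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def table1_fixture() -> RecordSet:
    """The three-admission, two-patient worked example.

    Patient 231 is hospitalized twice for arteriosclerotic heart disease
    (atorvastatin + bisoprolol + clopidogrel, then atorvastatin +
    clopidogrel); patient 200 once (aspirin + atorvastatin + perindopril).
    Admission order follows ascending hospital ID, the only ordering the
    source table implies.
    """
    rows = [
        ("564435", "231", ("Arteriosclerotic heart disease",),
         ("Atorvastatin", "Bisoprolol", "Clopidogrel")),
        ("561657", "200", ("Arteriosclerotic heart disease",),
         ("Aspirin", "Atorvastatin", "Perindopril")),
        ("564677", "231", ("Arteriosclerotic heart disease",),
         ("Atorvastatin", "Clopidogrel")),
    ]
    order = {hid: i + 1 for i, hid in enumerate(sorted(h for h, *_ in rows))}
    return RecordSet(
        AdmissionRecord(
            hospital_id=h,
            patient_id=p,
            admission_time=order[h],
            diagnoses=d,
            medicines=m,
        )
        for h, p, d, m in rows
    )
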