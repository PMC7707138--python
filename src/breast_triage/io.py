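"""CSV schemas, config files and report serialization.

Two tabular interchange formats:

* patients CSV - one row per presentation, fixed header order
  (:data:`PATIENTS_HEADER`); booleans accept true/false and 1/0,
  enums are case-insensitive.
* decisions CSV - ``patient_id, source, outcome`` with outcomes spelled
  exactly as the four enum names and sources software / gp /
  surgeon_gold.

Writers prepend a single ``#`` provenance comment (tool version, config
hash, seed); readers skip ``#`` lines, so a write-read round trip is
the identity on valid data. Rows that fail parsing or validation are
collected into a row-level error report with row number and field name,
never silently dropped.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import CohortParams, SimulatedPatient
from .core import (
    EngineConfig,
    FamilyHistory,
    NippleDischarge,
    PatientRecord,
    RecordValidationError,
    Sex,
    SymptomProfile,
    TriageOutcome,
)
from .evaluation import DecisionSet, DecisionSource, GPUrgency

PATIENTS_HEADER = [
    "patient_id",
    "age_years",
    "sex",
    "lump_breast",
    "lump_axilla",
    "lump_explained",
    "pain",
    "pain_bilateral_cyclical",
    "nipple_discharge",
    "nipple_discharge_unilateral",
    "nipple_retraction",
    "nipple_change_other",
    "skin_change_suspicious",
    "family_history",
    "prior_breast_condition",
    "duration_weeks",
]

DECISIONS_HEADER = ["patient_id", "source", "outcome"]

_BOOL_FIELDS = {
    "lump_breast",
    "lump_axilla",
    "lump_explained",
    "pain",
    "pain_bilateral_cyclical",
    "nipple_discharge_unilateral",
    "nipple_retraction",
    "nipple_change_other",
    "skin_change_suspicious",
    "prior_breast_condition",
}

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class FormatError(ValueError):
    """Malformed file-level structure (missing header, wrong columns)."""


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number
    field: str
    message: str


@dataclass
class PatientsTable:
    records: list[PatientRecord] = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected.

    Command-line flags override config-file values; a fully defaulted
    config is valid.
    """

    model_config = ConfigDict(extra="forbid")

    engine: EngineConfig = EngineConfig()
    cohort: Optional[CohortParams] = None
    continuity_correction: bool = False
    pooled_t: bool = False
    log_level: str = "INFO"


def load_run_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def _parse_bool(raw: str, fieldname: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"{fieldname}: cannot parse boolean from {raw!r}")


def _bool_str(value: bool) -> str:
    return "true" if value else "false"


def provenance_line(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    seed_part = "none" if seed is None else str(seed)
    return f"# breast-triage v{__version__} config_hash={digest} seed={seed_part}"


def _parse_row(row: dict[str, str]) -> PatientRecord:
    symptoms: dict = {}
    for name in _BOOL_FIELDS - {"prior_breast_condition"}:
        symptoms[name] = _parse_bool(row[name], name)
    raw_discharge = row["nipple_discharge"].strip().lower()
    try:
        symptoms["nipple_discharge"] = NippleDischarge(raw_discharge)
    except ValueError:
        raise ValueError(f"nipple_discharge: unknown value {row['nipple_discharge']!r}")
    try:
        symptoms["duration_weeks"] = float(row["duration_weeks"])
    except ValueError:
        raise ValueError(
            f"duration_weeks: cannot parse number from {row['duration_weeks']!r}"
        )
    try:
        age = int(row["age_years"])
    except ValueError:
        raise ValueError(f"age_years: cannot parse integer from {row['age_years']!r}")
    try:
        sex = Sex(row["sex"].strip().lower())
    except ValueError:
        raise ValueError(f"sex: unknown value {row['sex']!r}")
    try:
        fh = FamilyHistory(row["family_history"].strip().lower())
    except ValueError:
        raise ValueError(f"family_history: unknown value {row['family_history']!r}")
    from .core import validate_record

    return validate_record(
        dict(
            patient_id=row["patient_id"],
            age_years=age,
            sex=sex,
            symptoms=symptoms,
            family_history=fh,
            prior_breast_condition=_parse_bool(
                row["prior_breast_condition"], "prior_breast_condition"
            ),
        )
    )


def _read_csv_rows(path: Union[str, Path], header: list[str]) -> list[list[str]]:
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.reader(lines)
    try:
        got_header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected header {header}")
    if got_header != header:
        raise FormatError(f"{path}: malformed header {got_header}, expected {header}")
    return list(reader)


def read_patients_csv(path: Union[str, Path]) -> PatientsTable:
    """Parse a patients CSV into validated records plus a row error report."""
    table = PatientsTable()
    for i, raw in enumerate(_read_csv_rows(path, PATIENTS_HEADER), start=1):
        if len(raw) != len(PATIENTS_HEADER):
            table.errors.append(RowError(i, "*", "wrong number of fields"))
            continue
        row = dict(zip(PATIENTS_HEADER, raw))
        try:
            table.records.append(_parse_row(row))
        except RecordValidationError as exc:
            table.errors.append(RowError(i, "record", str(exc)))
        except ValueError as exc:
            fieldname, _, msg = str(exc).partition(": ")
            table.errors.append(RowError(i, fieldname, msg or str(exc)))
    return table


def record_to_row(record: PatientRecord) -> list[str]:
    s = record.symptoms
    return [
        record.patient_id,
        str(record.age_years),
        record.sex.value,
        _bool_str(s.lump_breast),
        _bool_str(s.lump_axilla),
        _bool_str(s.lump_explained),
        _bool_str(s.pain),
        _bool_str(s.pain_bilateral_cyclical),
        s.nipple_discharge.value,
        _bool_str(s.nipple_discharge_unilateral),
        _bool_str(s.nipple_retraction),
        _bool_str(s.nipple_change_other),
        _bool_str(s.skin_change_suspicious),
        record.family_history.value,
        _bool_str(record.prior_breast_condition),
        f"{s.duration_weeks:g}",
    ]


def write_patients_csv(
    records: list[PatientRecord],
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PATIENTS_HEADER)
        for rec in records:
            writer.writerow(record_to_row(rec))


def write_decisions_csv(
    rows: list[tuple[str, str, TriageOutcome]],
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[dict] = None,
    extra_columns: Optional[dict[str, list[str]]] = None,
) -> None:
    """Write (patient_id, source, outcome) rows; ``extra_columns`` appends
    aligned columns such as a rule trace."""
    header = list(DECISIONS_HEADER) + sorted(extra_columns or {})
    with open(path, "w", newline="") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for i, (pid, source, outcome) in enumerate(rows):
            extras = [extra_columns[c][i] for c in sorted(extra_columns or {})]
            writer.writerow([pid, source, TriageOutcome(outcome).value] + extras)


def read_decisions_csv(path: Union[str, Path]) -> dict[str, DecisionSet]:
    """Read a decisions CSV into one DecisionSet per source present."""
    per_source: dict[str, dict[str, TriageOutcome]] = {}
    rows = _read_csv_rows_loose(path)
    for i, row in enumerate(rows, start=1):
        try:
            source = DecisionSource(row["source"].strip().lower()).value
            outcome = TriageOutcome(row["outcome"].strip().upper())
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}")
        bucket = per_source.setdefault(source, {})
        pid = row["patient_id"]
        if pid in bucket:
            raise FormatError(f"{path}: row {i}: duplicate patient_id {pid!r} for {source}")
        bucket[pid] = outcome
    return {
        source: DecisionSet(DecisionSource(source), decisions)
        for source, decisions in per_source.items()
    }


def _read_csv_rows_loose(path: Union[str, Path]) -> list[dict[str, str]]:
    """Decisions reader tolerating extra trailing columns (e.g. trace)."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty file")
    if header[: len(DECISIONS_HEADER)] != DECISIONS_HEADER:
        raise FormatError(
            f"{path}: malformed header {header}, expected prefix {DECISIONS_HEADER}"
        )
    return [dict(zip(header, row)) for row in reader]


def cohort_to_decision_rows(
    cohort: list[SimulatedPatient],
) -> list[tuple[str, str, TriageOutcome]]:
    """Decision rows for all three sources of a simulated cohort.

    The GP's binary urgency maps onto the two specialist outcomes
    (urgent -> URGENT_SPECIALIST, routine -> ROUTINE_SPECIALIST), which
    is how a GP referral letter is read at the clinic.
    """
    from .core import triage  # local import to keep module load cheap

    rows: list[tuple[str, str, TriageOutcome]] = []
    for p in cohort:
        rows.append((p.record.patient_id, "surgeon_gold", p.gold))
    for p in cohort:
        gp_outcome = (
            TriageOutcome.URGENT_SPECIALIST
            if p.gp_decision == GPUrgency.URGENT
            else TriageOutcome.ROUTINE_SPECIALIST
        )
        rows.append((p.record.patient_id, "gp", gp_outcome))
    for p in cohort:
        rows.append((p.record.patient_id, "software", triage(p.record)[0]))
    return rows


def write_report(report: dict, path: Union[str, Path]) -> None:
    """Serialize a report document (accuracy/audit/summary) as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_provenance(
    path: Union[str, Path], params: CohortParams, seed: int
) -> None:
    """Sidecar recording the exact generator parameters and seed."""
    payload = {"params": params.model_dump(), "seed": seed, "version": __version__}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
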