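"""Readers and writers for record and result files, plus run configuration.

Stage-record files are comma-separated UTF-8 text with one header row and
one row per (subject, tooth, scheme):

    subject_id,sex,age_years,age_months,fdi,scheme,stage,present

Chronological age is assembled as ``age_years + age_months/12``.  A
one-subject-per-document JSON variant mirrors the same fields.  Result
files round-trip through the same readers; display rounding is applied
at write time only.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .estimators import EstimateResult, Method
from .evaluation import ComparisonResult, ErrorRecord
from .reference_model import (
    DentitionRecord,
    Scheme,
    Sex,
    StageAssessment,
    ToothId,
    parse_stage_token,
    stage_token,
)

__all__ = [
    "RecordParseError",
    "RunConfig",
    "read_records",
    "write_records",
    "read_record_json",
    "write_record_json",
    "write_results",
    "read_estimates",
]

RECORD_COLUMNS = ("subject_id", "sex", "age_years", "age_months", "fdi", "scheme", "stage", "present")


class RecordParseError(ValueError):
    """A record file row failed to parse; the message names file and line."""


@dataclass
class RunConfig:
    """Configuration of a full estimation + evaluation run."""

    methods: tuple[str, ...] = ("nolla", "demirjian", "atlas")
    tables_path: str | None = None
    records_path: str | None = None
    margins: tuple[float, ...] = (1.0, 2.0)
    olze_trigger_age: float = 16.0
    margin_inclusive: bool = True
    out_dir: str = "."
    seed: int | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.margins):
            raise ValueError("margins must be positive")
        if self.olze_trigger_age <= 0:
            raise ValueError("olze_trigger_age must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "margins"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _parse_row(row: Mapping[str, str], where: str) -> tuple[str, Sex, float, StageAssessment | None]:
    try:
        sex = Sex(row["sex"].strip().lower())
    except ValueError:
        raise RecordParseError(f"{where}: unknown sex {row['sex']!r}") from None
    try:
        years, months = int(row["age_years"]), int(row["age_months"])
        if not (0 <= months <= 11):
            raise ValueError
    except (ValueError, KeyError):
        raise RecordParseError(f"{where}: bad age fields {row.get('age_years')!r}/{row.get('age_months')!r}") from None
    age = years + months / 12.0
    try:
        tooth = ToothId(int(row["fdi"]))
    except (ValueError, KeyError):
        raise RecordParseError(f"{where}: invalid FDI code {row.get('fdi')!r}") from None
    try:
        scheme = Scheme(row["scheme"].strip().upper())
    except ValueError:
        raise RecordParseError(f"{where}: unknown scheme {row['scheme']!r}") from None
    present = row.get("present", "true").strip().lower() in ("1", "true", "yes")
    if not present:
        return row["subject_id"], sex, age, StageAssessment(tooth, scheme, None, present=False)
    try:
        stage, prox = parse_stage_token(scheme, row["stage"])
    except ValueError as exc:
        raise RecordParseError(f"{where}: {exc}") from None
    return row["subject_id"], sex, age, StageAssessment(tooth, scheme, stage, proximity=prox)


def read_records(path: str | Path) -> list[DentitionRecord]:
    """Read a delimited stage-record file into dentition records.

    Malformed rows raise :class:`RecordParseError` naming the file and
    line; a duplicated (subject, tooth, scheme) is an error.
    """
    path = Path(path)
    subjects: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(RECORD_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise RecordParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            sid, sex, age, assessment = _parse_row(row, where)
            entry = subjects.setdefault(sid, {"sex": sex, "age": age, "assessments": [], "keys": set()})
            if entry["sex"] != sex or abs(entry["age"] - age) > 1e-9:
                raise RecordParseError(f"{where}: inconsistent sex/age for subject {sid!r}")
            if assessment is not None:
                key = (assessment.tooth.fdi_code, assessment.scheme)
                if key in entry["keys"]:
                    raise RecordParseError(
                        f"{where}: duplicate assessment for subject {sid!r}, tooth {assessment.tooth}, "
                        f"scheme {assessment.scheme.value}"
                    )
                entry["keys"].add(key)
                if assessment.present:
                    entry["assessments"].append(assessment)
    return [
        DentitionRecord(subject_id=sid, sex=e["sex"], age_true=e["age"], assessments=e["assessments"])
        for sid, e in subjects.items()
    ]


def write_records(records: Iterable[DentitionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            years = int(r.age_true)
            months = int(round((r.age_true - years) * 12))
            for a in r.assessments:
                writer.writerow(
                    [r.subject_id, r.sex.value, years, months, a.tooth.fdi_code,
                     a.scheme.value, stage_token(a), str(a.present).lower()]
                )


def write_record_json(record: DentitionRecord, path: str | Path) -> None:
    """One-subject JSON variant of the record format."""
    years = int(record.age_true)
    doc = {
        "subject_id": record.subject_id,
        "sex": record.sex.value,
        "age_years": years,
        "age_months": int(round((record.age_true - years) * 12)),
        "assessments": [
            {"fdi": a.tooth.fdi_code, "scheme": a.scheme.value, "stage": stage_token(a), "present": a.present}
            for a in record.assessments
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_record_json(path: str | Path) -> DentitionRecord:
    doc = json.loads(Path(path).read_text())
    assessments = []
    for a in doc["assessments"]:
        scheme = Scheme(a["scheme"])
        if not a.get("present", True):
            continue
        stage, prox = parse_stage_token(scheme, str(a["stage"]))
        assessments.append(StageAssessment(ToothId(int(a["fdi"])), scheme, stage, proximity=prox))
    return DentitionRecord(
        subject_id=doc["subject_id"],
        sex=Sex(doc["sex"]),
        age_true=int(doc["age_years"]) + int(doc["age_months"]) / 12.0,
        assessments=assessments,
    )


def _estimates_frame(estimates: Iterable[EstimateResult]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        inter = e.intermediate
        summary = ""
        if e.method is Method.NOLLA and "sum_of_values" in inter:
            summary = f"sum={inter['sum_of_values']:.1f}"
        elif e.method is Method.DEMIRJIAN_OLZE and "maturity_score" in inter:
            summary = f"S={inter['maturity_score']:.2f}"
            if inter.get("olze_triggered"):
                summary += f";olze_tooth={inter.get('olze_tooth')}"
        elif "matched_chart_ages" in inter:
            summary = "charts=" + "|".join(f"{a:g}" for a in inter["matched_chart_ages"])
        rows.append(
            {
                "subject_id": e.subject_id,
                "method": e.method.value,
                "age_est": round(e.age_est, 4),
                "intermediate": summary,
                "substitutions": "|".join(str(s) for s in e.substitutions),
                "clamped": e.clamped,
                "olze_triggered": bool(inter.get("olze_triggered", False)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "method", "age_est", "intermediate", "substitutions", "clamped", "olze_triggered"],
    )


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_results(
    estimates: Iterable[EstimateResult],
    errors: Iterable[ErrorRecord],
    tables: Mapping[str, pd.DataFrame],
    comparisons: Mapping[str, ComparisonResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write estimates.csv, errors.csv, table1.csv, table2.csv, comparisons.csv.

    Output is deterministic for identical inputs and parseable by this
    module's own readers.  Empty inputs yield headers-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["estimates"] = out / "estimates.csv"
    _estimates_frame(estimates).to_csv(paths["estimates"], index=False)

    paths["errors"] = out / "errors.csv"
    err_rows = [
        {
            "subject_id": e.subject_id,
            "method": e.method.value,
            "delta": round(e.delta, 4),
            "abs_delta": round(e.abs_delta, 4),
            "age_category": e.age_category,
        }
        for e in errors
    ]
    pd.DataFrame(
        err_rows, columns=["subject_id", "method", "delta", "abs_delta", "age_category"]
    ).to_csv(paths["errors"], index=False)

    for name in ("table1", "table2"):
        paths[name] = out / f"{name}.csv"
        df = tables.get(name, pd.DataFrame())
        df.to_csv(paths[name], index=False)

    paths["comparisons"] = out / "comparisons.csv"
    cmp_rows = [
        {
            "comparison": name,
            "test": c.test,
            "statistic": round(c.statistic, 4),
            "p_value": c.p_value,
            "n_pairs": c.n_pairs,
            "applicability": c.applicability,
        }
        for name, c in comparisons.items()
    ]
    pd.DataFrame(
        cmp_rows, columns=["comparison", "test", "statistic", "p_value", "n_pairs", "applicability"]
    ).to_csv(paths["comparisons"], index=False)
    return paths
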