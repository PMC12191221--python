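"""CSV readers/writers and run configuration.

One row per examined node; comma-separated, UTF-8, "." decimal point,
booleans serialized as 0/1. An empty cell means absent: false for
booleans, "Doppler not performed" for the vascular pattern, and no
label for histopathology/cohort. The clinical-context columns and the
histopathology/cohort columns may be omitted entirely.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd
import yaml

from .classifier import (
    DEFAULT_RULE_CONFIG,
    ClassificationResult,
    RuleConfig,
    binarize,
    classify,
)
from .domain import (
    ArchitecturalFindings,
    ClinicalContext,
    Cohort,
    Histopathology,
    LymphNodeRecord,
    MorphometricFeatures,
    Region,
    SubjectiveGrades,
    Violation,
    validate_record,
)
from .errors import ConfigError, ParseError, SchemaError

__all__ = [
    "CSV_COLUMNS",
    "RunConfig",
    "LoadedNodes",
    "read_nodes",
    "write_nodes",
    "records_to_frame",
    "classify_records",
    "write_classified",
    "read_classified",
    "rule_config_from_yaml",
    "rule_config_to_yaml",
]

logger = logging.getLogger("lnrads")

_MM_COLUMNS = ("sad_mm", "lad_mm", "ctd_mm", "mtd_mm")
_GRADE_COLUMNS = (
    "shape_grade",
    "cortex_irregularity_grade",
    "echogenicity_grade",
    "inhomogeneity_grade",
    "border_grade",
)
_FINDING_COLUMNS = (
    "hilum_present",
    "steatotic_hilum",
    "fct",
    "lct",
    "microcalcifications",
    "fluid_collections",
    "necrosis",
    "extracapsular_infiltration",
)
_CLINICAL_COLUMNS = (
    "oncological_history",
    "hematological_history",
    "active_regional_neoplasm",
    "elevated_or_rising_markers",
    "other_suspicious_regional_ln",
    "systemic_symptoms",
)

CSV_COLUMNS = (
    "node_id",
    "region",
    *_MM_COLUMNS,
    *_GRADE_COLUMNS,
    "vascular_pattern",
    *_FINDING_COLUMNS,
    *_CLINICAL_COLUMNS,
    "histopathology",
    "cohort",
)

#: Columns that may be absent from an input file (documented defaults apply).
_OPTIONAL_COLUMNS = frozenset((*_CLINICAL_COLUMNS, "vascular_pattern", "histopathology", "cohort"))
_REQUIRED_COLUMNS = tuple(c for c in CSV_COLUMNS if c not in _OPTIONAL_COLUMNS)


@dataclass(frozen=True)
class RunConfig:
    """Full provenance of one pipeline run, echoed into every report."""

    rule_config: RuleConfig = DEFAULT_RULE_CONFIG
    scheme: str = "statistical"
    ci_level: float = 0.95
    seed: Optional[int] = None

    def validate(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0, 1)")
        self.rule_config.validate()


@dataclass
class LoadedNodes:
    """Parsed records together with the per-row validation report."""

    records: list[LymphNodeRecord]
    violations: list[tuple[int, Violation]] = field(default_factory=list)

    def __iter__(self) -> Iterator[LymphNodeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_float(cell: str, row: int, col: str) -> float:
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {col!r}: cannot parse {cell!r} as a number") from exc


def _parse_int(cell: str, row: int, col: str) -> int:
    try:
        return int(cell)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {col!r}: cannot parse {cell!r} as an integer") from exc


def _parse_bool(cell: str, row: int, col: str) -> bool:
    if cell == "" or cell == "0":
        return False
    if cell == "1":
        return True
    raise ParseError(f"row {row}, column {col!r}: booleans must be 0/1, got {cell!r}")


def read_nodes(path: Union[str, Path]) -> LoadedNodes:
    """Read a node table, validating each record.

    Rows that breach data-model invariants are still returned; the
    breaches are collected (and logged) per row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)

    def cell(row_values, col: str) -> str:
        return str(row_values[col]).strip() if col in df.columns else ""

    records: list[LymphNodeRecord] = []
    violations: list[tuple[int, Violation]] = []
    for i, row_values in enumerate(df.to_dict("records")):
        rownum = i + 2  # 1-based, after the header line
        region_text = cell(row_values, "region")
        try:
            region = Region(region_text)
        except ValueError as exc:
            raise ParseError(
                f"row {rownum}, column 'region': unknown region {region_text!r}"
            ) from exc
        vp_cell = cell(row_values, "vascular_pattern")
        histo_cell = cell(row_values, "histopathology")
        cohort_cell = cell(row_values, "cohort")
        record = LymphNodeRecord(
            node_id=cell(row_values, "node_id"),
            region=region,
            features=MorphometricFeatures(
                **{c: _parse_float(cell(row_values, c), rownum, c) for c in _MM_COLUMNS}
            ),
            grades=SubjectiveGrades(
                **{c: _parse_int(cell(row_values, c), rownum, c) for c in _GRADE_COLUMNS},
                vascular_pattern=(
                    _parse_int(vp_cell, rownum, "vascular_pattern") if vp_cell else None
                ),
            ),
            findings=ArchitecturalFindings(
                **{c: _parse_bool(cell(row_values, c), rownum, c) for c in _FINDING_COLUMNS}
            ),
            clinical=ClinicalContext(
                **{c: _parse_bool(cell(row_values, c), rownum, c) for c in _CLINICAL_COLUMNS}
            ),
            histopathology=Histopathology(histo_cell) if histo_cell else None,
            cohort=Cohort(cohort_cell) if cohort_cell else None,
        )
        for violation in validate_record(record):
            violations.append((rownum, violation))
            logger.warning("row %d (%s): %s", rownum, record.node_id, violation)
        records.append(record)
    return LoadedNodes(records=records, violations=violations)


def _fmt_mm(value: float) -> str:
    return f"{value:.10g}"


def _record_row(r: LymphNodeRecord) -> dict[str, str]:
    row = {
        "node_id": r.node_id,
        "region": r.region.value,
        **{c: _fmt_mm(getattr(r.features, c)) for c in _MM_COLUMNS},
        **{c: str(getattr(r.grades, c)) for c in _GRADE_COLUMNS},
        "vascular_pattern": (
            "" if r.grades.vascular_pattern is None else str(r.grades.vascular_pattern)
        ),
        **{c: str(int(getattr(r.findings, c))) for c in _FINDING_COLUMNS},
        **{c: str(int(getattr(r.clinical, c))) for c in _CLINICAL_COLUMNS},
        "histopathology": "" if r.histopathology is None else r.histopathology.value,
        "cohort": "" if r.cohort is None else r.cohort.value,
    }
    return row


def records_to_frame(records: Sequence[LymphNodeRecord]) -> pd.DataFrame:
    return pd.DataFrame([_record_row(r) for r in records], columns=list(CSV_COLUMNS))


def write_nodes(records: Sequence[LymphNodeRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def classify_records(
    records: Sequence[LymphNodeRecord], config: RuleConfig = DEFAULT_RULE_CONFIG
) -> list[ClassificationResult]:
    return [classify(r, config) for r in records]


def write_classified(
    records: Sequence[LymphNodeRecord],
    results: Sequence[ClassificationResult],
    path: Union[str, Path],
) -> None:
    """Write the node table with appended classification columns."""
    df = records_to_frame(records)
    df["category"] = [res.category.value for res in results]
    df["positive_statistical"] = [
        str(int(binarize(res.category, "statistical") == "positive")) for res in results
    ]
    df["positive_management"] = [
        str(int(binarize(res.category, "management") == "positive")) for res in results
    ]
    df["triggered_rules"] = [";".join(res.triggered_rules) for res in results]
    df["risk_band"] = [res.malignancy_risk_band for res in results]
    df.to_csv(path, index=False)


def read_classified(path: Union[str, Path]) -> pd.DataFrame:
    """Read a classified table back (category column required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "category" not in df.columns:
        raise SchemaError(f"{path}: missing 'category' column; run `lnrads classify` first")
    return df


_RULE_FIELDS = tuple(RuleConfig.__dataclass_fields__)


def rule_config_from_yaml(path: Union[str, Path]) -> RuleConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: rule configuration must be a mapping")
    unknown = set(data) - set(_RULE_FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown rule-config keys {sorted(unknown)}")
    config = RuleConfig(**data)
    config.validate()
    return config


def rule_config_to_yaml(config: RuleConfig) -> str:
    return yaml.safe_dump(
        {name: getattr(config, name) for name in _RULE_FIELDS}, sort_keys=False
    )
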