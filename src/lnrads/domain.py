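"""Data model for superficial lymph-node ultrasound records.

A record bundles what a radiologist measures and grades on B-mode /
Doppler ultrasound of one superficial lymph node:

* four morphometric lengths in millimetres — short-axis diameter (SAD),
  long-axis diameter (LAD), maximal cortical thickness (CTD) and
  medullary/hilar thickness (MTD, with 0 encoding an invisible hilum);
* six subjective 1-5 ordinal grades (shape, cortex irregularity,
  echogenicity, inhomogeneity, borders, vascular pattern), where grade 1
  is always the most benign pole;
* boolean architectural findings (hilum, steatotic hilum, focal/local
  cortical thickening, microcalcifications, fluid, necrosis,
  extracapsular infiltration);
* boolean clinical-context flags (oncological history, active regional
  neoplasm, rising markers, ...);
* optional histopathology truth and neoplasm-cohort tag.

Two derived ratios are used throughout: SAD/LAD (node "roundness") and
MTD/(MTD + CTD) (how much of the node is still medulla).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Optional

from .errors import DegenerateMeasurementError

__all__ = [
    "Region",
    "Histopathology",
    "Cohort",
    "MALIGNANT_COHORTS",
    "LNRADSCategory",
    "CATEGORY_ORDER",
    "MorphometricFeatures",
    "DerivedRatios",
    "SubjectiveGrades",
    "ArchitecturalFindings",
    "ClinicalContext",
    "LymphNodeRecord",
    "Violation",
    "derive_ratios",
    "validate_record",
]


class Region(Enum):
    NECK = "neck"
    PERICLAVICULAR = "periclavicular"
    AXILLA = "axilla"
    INGUINAL = "inguinal"


class Histopathology(Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class Cohort(Enum):
    CANCER = "cancer"
    LEUKEMIA_LYMPHOMA = "leukemia_lymphoma"
    MELANOMA_SARCOMA = "melanoma_sarcoma"
    NONSPECIFIC = "nonspecific"
    BENIGN = "benign"


#: Cohort tags that imply a malignant histopathology label.
MALIGNANT_COHORTS = frozenset(
    {Cohort.CANCER, Cohort.LEUKEMIA_LYMPHOMA, Cohort.MELANOMA_SARCOMA, Cohort.NONSPECIFIC}
)


@total_ordering
class LNRADSCategory(Enum):
    """Ordinal reporting category with total order 1 < 2 < 3 < 4a < 4b < 5."""

    C1 = "1"
    C2 = "2"
    C3 = "3"
    C4A = "4a"
    C4B = "4b"
    C5 = "5"

    @property
    def rank(self) -> int:
        return _CATEGORY_RANK[self]

    def __lt__(self, other: "LNRADSCategory") -> bool:
        if not isinstance(other, LNRADSCategory):
            return NotImplemented
        return self.rank < other.rank

    def __hash__(self) -> int:  # Enum hash, kept explicit alongside __lt__
        return super().__hash__()

    def __str__(self) -> str:
        return self.value

    @classmethod
    def from_str(cls, text: str) -> "LNRADSCategory":
        try:
            return cls(str(text).strip().lower())
        except ValueError as exc:
            raise ValueError(f"unknown LN-RADS category {text!r}") from exc


CATEGORY_ORDER = (
    LNRADSCategory.C1,
    LNRADSCategory.C2,
    LNRADSCategory.C3,
    LNRADSCategory.C4A,
    LNRADSCategory.C4B,
    LNRADSCategory.C5,
)
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class MorphometricFeatures:
    """Calliper measurements in millimetres, accepted to 0.1 mm precision.

    ``mtd_mm = 0`` is the canonical encoding of an invisible hilum.
    """

    sad_mm: float
    lad_mm: float
    ctd_mm: float
    mtd_mm: float


@dataclass(frozen=True)
class DerivedRatios:
    s_over_l: float
    medulla_fraction: float


@dataclass(frozen=True)
class SubjectiveGrades:
    """Ordinal 1-5 grades; grade 1 is the most benign pole of each scale.

    ``vascular_pattern`` is None when Doppler was not performed — a
    first-class state, never imputed. When present: 1 no flow, 2 hilar
    "small tree", 3 hilar-cortical "big tree", 4 peripheral, 5 chaotic.
    """

    shape_grade: int = 1
    cortex_irregularity_grade: int = 1
    echogenicity_grade: int = 1
    inhomogeneity_grade: int = 1
    border_grade: int = 1
    vascular_pattern: Optional[int] = None


@dataclass(frozen=True)
class ArchitecturalFindings:
    hilum_present: bool = True
    steatotic_hilum: bool = False
    fct: bool = False
    lct: bool = False
    microcalcifications: bool = False
    fluid_collections: bool = False
    necrosis: bool = False
    extracapsular_infiltration: bool = False


@dataclass(frozen=True)
class ClinicalContext:
    oncological_history: bool = False
    hematological_history: bool = False
    active_regional_neoplasm: bool = False
    elevated_or_rising_markers: bool = False
    other_suspicious_regional_ln: bool = False
    systemic_symptoms: bool = False

    @property
    def any_flag(self) -> bool:
        return any(
            (
                self.oncological_history,
                self.hematological_history,
                self.active_regional_neoplasm,
                self.elevated_or_rising_markers,
                self.other_suspicious_regional_ln,
                self.systemic_symptoms,
            )
        )


@dataclass(frozen=True)
class LymphNodeRecord:
    node_id: str
    region: Region
    features: MorphometricFeatures
    grades: SubjectiveGrades = field(default_factory=SubjectiveGrades)
    findings: ArchitecturalFindings = field(default_factory=ArchitecturalFindings)
    clinical: ClinicalContext = field(default_factory=ClinicalContext)
    histopathology: Optional[Histopathology] = None
    cohort: Optional[Cohort] = None


@dataclass(frozen=True)
class Violation:
    """One breached invariant: which field, and what was expected."""

    field: str
    invariant: str

    def __str__(self) -> str:
        return f"{self.field}: {self.invariant}"


def derive_ratios(features: MorphometricFeatures) -> DerivedRatios:
    """Compute SAD/LAD and MTD/(MTD + CTD), exactly and without rounding.

    Raises
    ------
    DegenerateMeasurementError
        If ``lad_mm <= 0`` (roundness undefined) or ``ctd_mm + mtd_mm <= 0``
        (medulla fraction undefined).
    """
    if features.lad_mm <= 0:
        raise DegenerateMeasurementError("lad_mm must be > 0 to form SAD/LAD")
    denom = features.ctd_mm + features.mtd_mm
    if denom <= 0:
        raise DegenerateMeasurementError(
            "ctd_mm + mtd_mm must be > 0 to form MTD/(MTD + CTD)"
        )
    return DerivedRatios(
        s_over_l=features.sad_mm / features.lad_mm,
        medulla_fraction=features.mtd_mm / denom,
    )


_GRADE_FIELDS = (
    "shape_grade",
    "cortex_irregularity_grade",
    "echogenicity_grade",
    "inhomogeneity_grade",
    "border_grade",
)


def validate_record(record: LymphNodeRecord) -> list[Violation]:
    """Return every breached invariant of *record* (empty list if consistent).

    Violations are reported, not raised, so a whole table can be screened
    in one pass.
    """
    v: list[Violation] = []
    f = record.features
    if not f.sad_mm > 0:
        v.append(Violation("features.sad_mm", "short-axis diameter must be > 0"))
    if not f.lad_mm > 0:
        v.append(Violation("features.lad_mm", "long-axis diameter must be > 0"))
    if f.ctd_mm < 0:
        v.append(Violation("features.ctd_mm", "cortical thickness must be >= 0"))
    if f.mtd_mm < 0:
        v.append(Violation("features.mtd_mm", "medullary thickness must be >= 0"))
    if f.lad_mm < f.sad_mm:
        v.append(
            Violation("features.lad_mm", "axis order: lad_mm must be >= sad_mm")
        )
    if f.ctd_mm > f.sad_mm:
        v.append(Violation("features.ctd_mm", "ctd_mm must not exceed sad_mm"))
    if f.mtd_mm > f.sad_mm:
        v.append(Violation("features.mtd_mm", "mtd_mm must not exceed sad_mm"))

    for name in _GRADE_FIELDS:
        grade = getattr(record.grades, name)
        if not (isinstance(grade, int) and 1 <= grade <= 5):
            v.append(Violation(f"grades.{name}", "grade must be an integer in 1..5"))
    vp = record.grades.vascular_pattern
    if vp is not None and not (isinstance(vp, int) and 1 <= vp <= 5):
        v.append(
            Violation(
                "grades.vascular_pattern",
                "vascular pattern must be absent or an integer in 1..5",
            )
        )

    if record.findings.steatotic_hilum and not record.findings.hilum_present:
        v.append(
            Violation(
                "findings.steatotic_hilum", "steatotic hilum requires hilum_present"
            )
        )
    if not record.findings.hilum_present and f.mtd_mm != 0:
        v.append(
            Violation(
                "findings.hilum_present",
                "hilum/MTD consistency: hilum_present = false requires mtd_mm = 0",
            )
        )
    if record.findings.hilum_present and f.mtd_mm == 0:
        v.append(
            Violation(
                "findings.hilum_present",
                "hilum/MTD consistency: mtd_mm = 0 encodes an absent hilum",
            )
        )

    if record.cohort is Cohort.BENIGN and record.histopathology is not Histopathology.BENIGN:
        v.append(
            Violation("cohort", "cohort = benign requires histopathology = benign")
        )
    if record.cohort in MALIGNANT_COHORTS and record.histopathology is not Histopathology.MALIGNANT:
        v.append(
            Violation(
                "cohort", "a malignant cohort tag requires histopathology = malignant"
            )
        )
    return v
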