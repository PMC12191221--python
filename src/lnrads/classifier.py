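"""Deterministic LN-RADS category assignment.

The classifier formalizes the published category guidelines as a
malignant-first rule cascade over one validated record:

1. ``R5a`` — extracapsular infiltration is an unequivocal invasion sign
   and forces category 5 on its own.
2. ``R5b`` — an enlarged short axis (SAD above ``sad_enlarged_min_mm``,
   default > 9 mm, the study's own ROC-optimal SAD cutoff) together with
   at least ``high_risk_count_for_5`` high-risk features gives 5.
3. ``R4b`` — any single high-risk feature gives 4b.
4. ``R1``/``R2``/``R3`` — benign screens for normal, steatotic and
   reactive nodes.
5. ``R4a`` — the total fallback: anything that matches no other group,
   including category-3 morphology pushed up by clinical context
   ("better check than miss").

All "over X mm" comparisons are strict (>) and all "maximum X mm"
comparisons are inclusive (<=), mirroring the guideline wording.
An absent Doppler study is non-informative: it satisfies the benign
screens' vascular clause and contributes no high-risk feature.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .domain import LNRADSCategory, LymphNodeRecord, DerivedRatios
from .errors import ConfigError

__all__ = [
    "RuleConfig",
    "DEFAULT_RULE_CONFIG",
    "ClassificationResult",
    "MALIGNANT_FEATURE_IDS",
    "RISK_BANDS",
    "malignant_feature_set",
    "classify",
    "binarize",
    "is_positive",
    "risk_band",
    "BINARIZATION_SCHEMES",
]

#: High-risk ("malignant") feature identifiers, in a fixed report order.
MALIGNANT_FEATURE_IDS = (
    "CTD_OVER_4B_WITH_IRREGULARITY",
    "FCT",
    "NO_HILUM",
    "ROUND",
    "DEEP_HYPOECHOIC",
    "MICROCALCIFICATIONS",
    "FLUID",
    "NECROSIS",
    "ABNORMAL_VASCULARITY",
    "BLURRED_MARGINS",
)

#: Study-estimated malignancy risk per category (descriptive metadata).
RISK_BANDS = {
    LNRADSCategory.C1: "0%",
    LNRADSCategory.C2: "0%",
    LNRADSCategory.C3: "2%",
    LNRADSCategory.C4A: "31%",
    LNRADSCategory.C4B: "77%",
    LNRADSCategory.C5: "97%",
}

BINARIZATION_SCHEMES = ("statistical", "management")

_BENIGN_VASCULAR = {1, 2, 3}


@dataclass(frozen=True)
class RuleConfig:
    """Every numeric cutoff of the cascade, in millimetres where dimensional.

    Defaults follow the published guideline text: normal SAD up to 7 mm
    (the permissive end of the stated 6-7 mm), thin cortex <= 3 mm,
    4b-level cortical thickening > 4 mm, category-5-level thickening
    > 6 mm, oval shape encoded as SAD/LAD < 0.5 (equivalently L/S > 2),
    enlargement for category 5 as SAD > 9 mm, and "more malignancy
    features" operationalized as a count of at least 2.
    """

    sad_normal_max_mm: float = 7.0
    sad_enlarged_min_mm: float = 9.0
    ctd_thin_max_mm: float = 3.0
    ctd_4b_min_mm: float = 4.0
    ctd_5_min_mm: float = 6.0
    oval_s_over_l_max: float = 0.5
    high_risk_count_for_5: int = 2

    def validate(self) -> None:
        thresholds = (
            self.sad_normal_max_mm,
            self.sad_enlarged_min_mm,
            self.ctd_thin_max_mm,
            self.ctd_4b_min_mm,
            self.ctd_5_min_mm,
            self.oval_s_over_l_max,
        )
        if any(t <= 0 for t in thresholds):
            raise ConfigError("all rule thresholds must be > 0")
        if not (self.ctd_thin_max_mm < self.ctd_4b_min_mm < self.ctd_5_min_mm):
            raise ConfigError(
                "cortical cutoffs must satisfy ctd_thin_max_mm < ctd_4b_min_mm < ctd_5_min_mm"
            )
        if self.high_risk_count_for_5 < 1:
            raise ConfigError("high_risk_count_for_5 must be a positive integer")

    def replace(self, **changes) -> "RuleConfig":
        cfg = replace(self, **changes)
        cfg.validate()
        return cfg


DEFAULT_RULE_CONFIG = RuleConfig()


@dataclass(frozen=True)
class ClassificationResult:
    category: LNRADSCategory
    triggered_rules: tuple[str, ...]
    malignancy_risk_band: str


def _s_over_l(record: LymphNodeRecord) -> float:
    return record.features.sad_mm / record.features.lad_mm


def malignant_feature_set(
    record: LymphNodeRecord,
    ratios: Optional[DerivedRatios] = None,
    config: RuleConfig = DEFAULT_RULE_CONFIG,
) -> set[str]:
    """Return the subset of high-risk features present on *record*.

    The fixed feature list covers cortical thickening over the 4b cutoff
    together with cortex irregularity (grade >= 3), focal cortical
    thickening, an absent hilum (MTD = 0), round shape (SAD/LAD >= 0.5),
    marked hypoechogenicity (grade >= 4, the near-anechoic "black hole"
    end of the scale), microcalcifications, fluid collections, necrosis,
    peripheral/chaotic vascularity (patterns 4-5) and blurred margins
    (border grade >= 4).
    """
    f, g, a = record.features, record.grades, record.findings
    s_over_l = ratios.s_over_l if ratios is not None else _s_over_l(record)
    present: set[str] = set()
    if f.ctd_mm > config.ctd_4b_min_mm and g.cortex_irregularity_grade >= 3:
        present.add("CTD_OVER_4B_WITH_IRREGULARITY")
    if a.fct:
        present.add("FCT")
    if f.mtd_mm == 0:
        present.add("NO_HILUM")
    if s_over_l >= config.oval_s_over_l_max:
        present.add("ROUND")
    if g.echogenicity_grade >= 4:
        present.add("DEEP_HYPOECHOIC")
    if a.microcalcifications:
        present.add("MICROCALCIFICATIONS")
    if a.fluid_collections:
        present.add("FLUID")
    if a.necrosis:
        present.add("NECROSIS")
    if g.vascular_pattern in (4, 5):
        present.add("ABNORMAL_VASCULARITY")
    if g.border_grade >= 4:
        present.add("BLURRED_MARGINS")
    return present


def _ordered(features: Iterable[str]) -> tuple[str, ...]:
    order = {name: i for i, name in enumerate(MALIGNANT_FEATURE_IDS)}
    return tuple(sorted(features, key=order.__getitem__))


def classify(
    record: LymphNodeRecord, config: RuleConfig = DEFAULT_RULE_CONFIG
) -> ClassificationResult:
    """Assign an LN-RADS category; pure and deterministic.

    The first element of ``triggered_rules`` is the rule that fired and
    fully determines the category; for 4b/5 the high-risk features that
    drove the decision follow it.
    """
    config.validate()
    f, g, a, c = record.features, record.grades, record.findings, record.clinical
    s_over_l = _s_over_l(record)
    high_risk = malignant_feature_set(record, config=config)

    def result(cat: LNRADSCategory, *rules: str) -> ClassificationResult:
        return ClassificationResult(
            category=cat,
            triggered_rules=tuple(rules),
            malignancy_risk_band=RISK_BANDS[cat],
        )

    # R5a: extracapsular infiltration is listed only under category 5.
    if a.extracapsular_infiltration:
        return result(LNRADSCategory.C5, "R5a:extracapsular_infiltration")
    # R5b: enlarged SAD plus "more malignancy features".
    if f.sad_mm > config.sad_enlarged_min_mm and len(high_risk) >= config.high_risk_count_for_5:
        return result(
            LNRADSCategory.C5, "R5b:enlarged_with_high_risk_features", *_ordered(high_risk)
        )
    # R4b: any single high-risk feature.
    if high_risk:
        return result(LNRADSCategory.C4B, "R4b:high_risk_features", *_ordered(high_risk))

    no_findings = not (
        a.fct or a.lct or a.microcalcifications or a.fluid_collections or a.necrosis
    )
    vascular_ok = g.vascular_pattern is None or g.vascular_pattern in _BENIGN_VASCULAR
    quiet_context = not c.any_flag

    # R1: normal node.
    if (
        f.sad_mm <= config.sad_normal_max_mm
        and s_over_l < config.oval_s_over_l_max
        and f.ctd_mm <= config.ctd_thin_max_mm
        and g.cortex_irregularity_grade <= 2
        and g.echogenicity_grade <= 2
        and g.border_grade <= 2
        and a.hilum_present
        and no_findings
        and vascular_ok
        and quiet_context
    ):
        return result(LNRADSCategory.C1, "R1:normal")
    # R2: steatotic node; no size limit once the hilum is fatty.
    if (
        f.ctd_mm <= config.ctd_thin_max_mm
        and g.cortex_irregularity_grade <= 2
        and a.steatotic_hilum
        and no_findings
        and g.border_grade <= 2
        and vascular_ok
        and quiet_context
    ):
        return result(LNRADSCategory.C2, "R2:steatotic")
    # R3: reactive node — thickened but regular cortex, preserved shape and hilum.
    if (
        f.ctd_mm > config.ctd_thin_max_mm
        and g.cortex_irregularity_grade <= 2
        and s_over_l < config.oval_s_over_l_max
        and a.hilum_present
        and g.echogenicity_grade <= 3
        and g.border_grade <= 2
        and not a.fct
        and not (a.microcalcifications or a.fluid_collections or a.necrosis)
        and vascular_ok
        and quiet_context
    ):
        return result(LNRADSCategory.C3, "R3:reactive")
    # R4a: everything else, including R3 morphology with clinical flags.
    return result(LNRADSCategory.C4A, "R4a:fallback")


def is_positive(category: LNRADSCategory, scheme: str) -> bool:
    """Test-positive under a binarization scheme.

    ``statistical`` counts 4b and 5 as positive (4a is treated as rather
    benign in the accuracy statistics); ``management`` counts 4a as well,
    since every 4a node is referred for biopsy or PET.
    """
    if scheme == "statistical":
        return category in (LNRADSCategory.C4B, LNRADSCategory.C5)
    if scheme == "management":
        return category in (LNRADSCategory.C4A, LNRADSCategory.C4B, LNRADSCategory.C5)
    raise ValueError(f"unknown binarization scheme {scheme!r}; expected one of {BINARIZATION_SCHEMES}")


def binarize(category: LNRADSCategory, scheme: str) -> str:
    return "positive" if is_positive(category, scheme) else "negative"


def risk_band(category: LNRADSCategory) -> str:
    """Study-estimated malignancy risk label for a category (metadata)."""
    return RISK_BANDS[category]
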