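"""Shared fixtures: record factory, the published count compositions."""
from __future__ import annotations

import pytest

from lnrads.domain import (
    ArchitecturalFindings,
    ClinicalContext,
    Cohort,
    Histopathology,
    LNRADSCategory,
    LymphNodeRecord,
    MorphometricFeatures,
    Region,
    SubjectiveGrades,
)

K = LNRADSCategory


def make_record(
    sad=5.0,
    lad=12.0,
    ctd=2.0,
    mtd=3.0,
    node_id="node-1",
    region=Region.NECK,
    histopathology=None,
    cohort=None,
    **kwargs,
):
    """Benign-template record; keyword overrides reach into the sub-objects."""
    grade_kw = {
        k: kwargs.pop(k)
        for k in list(kwargs)
        if k in SubjectiveGrades.__dataclass_fields__
    }
    finding_kw = {
        k: kwargs.pop(k)
        for k in list(kwargs)
        if k in ArchitecturalFindings.__dataclass_fields__
    }
    clinical_kw = {
        k: kwargs.pop(k)
        for k in list(kwargs)
        if k in ClinicalContext.__dataclass_fields__
    }
    if kwargs:
        raise TypeError(f"unknown record fields: {sorted(kwargs)}")
    finding_kw.setdefault("hilum_present", mtd > 0)
    return LymphNodeRecord(
        node_id=node_id,
        region=region,
        features=MorphometricFeatures(sad_mm=sad, lad_mm=lad, ctd_mm=ctd, mtd_mm=mtd),
        grades=SubjectiveGrades(**grade_kw),
        findings=ArchitecturalFindings(**finding_kw),
        clinical=ClinicalContext(**clinical_kw),
        histopathology=histopathology,
        cohort=cohort,
    )


#: Per-category (n_benign, n_malignant) composition of the published study.
STUDY_COMPOSITION = {
    K.C1: (33, 0),
    K.C2: (46, 0),
    K.C3: (107, 2),
    K.C4A: (95, 41),
    K.C4B: (42, 142),
    K.C5: (7, 204),
}

#: Printed per-cohort category counts of the malignant nodes.
STUDY_COHORT_CATEGORIES = {
    Cohort.CANCER: {K.C4A: 27, K.C4B: 99, K.C5: 107},
    Cohort.LEUKEMIA_LYMPHOMA: {K.C3: 1, K.C4A: 8, K.C4B: 22, K.C5: 62},
    Cohort.MELANOMA_SARCOMA: {K.C4A: 3, K.C4B: 15, K.C5: 30},
    Cohort.NONSPECIFIC: {K.C4A: 6, K.C4B: 6, K.C5: 5},
}


def expand_composition(composition=STUDY_COMPOSITION):
    """Category and truth vectors realizing a per-category count table."""
    categories, truth = [], []
    for cat, (n_benign, n_malignant) in composition.items():
        categories.extend([cat] * (n_benign + n_malignant))
        truth.extend(
            [Histopathology.BENIGN] * n_benign
            + [Histopathology.MALIGNANT] * n_malignant
        )
    return categories, truth


def expand_cohorts(cohort_categories=STUDY_COHORT_CATEGORIES):
    """Category/truth/cohort vectors realizing the per-cohort counts."""
    categories, truth, cohorts = [], [], []
    for cohort, counts in cohort_categories.items():
        for cat, n in counts.items():
            categories.extend([cat] * n)
            truth.extend([Histopathology.MALIGNANT] * n)
            cohorts.extend([cohort] * n)
    return categories, truth, cohorts


@pytest.fixture(scope="session")
def study_vectors():
    return expand_composition()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (study-sized groups), reused across tests."""
    from lnrads.synthetic import SyntheticCohortSpec, generate_cohort

    return generate_cohort(SyntheticCohortSpec(seed=7))
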