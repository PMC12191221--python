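# lnrads

Rule-based risk stratification of superficial lymph nodes on ultrasound,
with the full statistical toolkit needed to validate such a scale against
histopathology.

Radiologists examining lymph nodes (neck, peri-clavicular, axilla,
inguinal) lack a standardized way to communicate how suspicious a node
looks. LN-RADS is a BI-RADS-style ordinal reporting scale with six
categories — 1 (normal), 2 (steatotic), 3 (reactive), 4a (low suspicion),
4b (high suspicion), 5 (definitely malignant) — assigned from per-node
ultrasound features: the short- and long-axis diameters (SAD, LAD),
maximal cortical thickness (CTD), medullary/hilar thickness (MTD, 0 when
the hilum is invisible), the derived ratios SAD/LAD and MTD/(MTD + CTD),
five-level subjective grades (shape, cortex irregularity, echogenicity,
inhomogeneity, borders, Doppler vascular pattern) and boolean findings
(focal/local cortical thickening, microcalcifications, fluid, necrosis,
extracapsular infiltration) plus clinical context.

The package is aimed at radiology researchers evaluating structured
reporting scales. It provides:

- **`lnrads.domain`** — the validated per-node data model and derived ratios;
- **`lnrads.classifier`** — the category assignment as a deterministic,
  malignant-first rule cascade with every cutoff in a `RuleConfig`
  (normal SAD ≤ 7 mm, thin cortex ≤ 3 mm, 4b-level thickening > 4 mm,
  oval shape SAD/LAD < 0.5, category-5 enlargement SAD > 9 mm, ...), and
  two binarization schemes: *statistical* (4b–5 positive) and
  *management* (4a–5 referred for biopsy/PET);
- **`lnrads.evaluation`** — Table-style per-category confusion summaries,
  sensitivity/specificity/accuracy/PPV/NPV with Wilson score confidence
  intervals, per-group malignancy risk, per-cohort sensitivity;
- **`lnrads.thresholds`** — per-feature empirical ROC, concordance AUC
  with DeLong-type confidence interval, Youden-index optimal cutoffs
  (J = sensitivity + specificity − 1);
- **`lnrads.agreement`** — unweighted Cohen's kappa with the
  Fleiss–Cohen–Everitt standard error and the conventional
  interpretation bands;
- **`lnrads.synthetic`** — a seeded generator of synthetic cohorts
  matching published per-cohort feature means/SDs and vascular-pattern
  mixtures, plus multi-reader rating panels with adjacent-category noise;
- **`lnrads` CLI** — `simulate`, `classify`, `evaluate`, `thresholds`,
  `agreement`, `report`.

## Worked example

Classify one suspicious axillary node:

```python
from lnrads import (
    MorphometricFeatures, SubjectiveGrades, ArchitecturalFindings, ClinicalContext,
    LymphNodeRecord, Region, classify,
)

node = LymphNodeRecord(
    node_id="ax-017",
    region=Region.AXILLA,
    features=MorphometricFeatures(sad_mm=8.0, lad_mm=12.0, ctd_mm=6.0, mtd_mm=0.0),
    grades=SubjectiveGrades(cortex_irregularity_grade=4, echogenicity_grade=5,
                            vascular_pattern=5),
    findings=ArchitecturalFindings(hilum_present=False),
    clinical=ClinicalContext(),
)
result = classify(node)
print(result.category.value, result.malignancy_risk_band)
print(result.triggered_rules)
```

prints

```
4b 77%
('R4b:high_risk_features', 'CTD_OVER_4B_WITH_IRREGULARITY', 'NO_HILUM', 'ROUND', 'DEEP_HYPOECHOIC', 'ABNORMAL_VASCULARITY')
```

— the node carries five high-risk features (thickened irregular cortex,
absent hilum, round shape, near-anechoic cortex, chaotic vascularity)
but its short axis (8 mm) is not enlarged, so it lands in 4b rather
than 5, with an estimated 77% malignancy risk. Evaluating a full
category/outcome composition:

```python
from lnrads.domain import Histopathology, LNRADSCategory as K
from lnrads.evaluation import confusion_summary, diagnostic_metrics, percent_display

composition = {K.C1: (33, 0), K.C2: (46, 0), K.C3: (107, 2),
               K.C4A: (95, 41), K.C4B: (42, 142), K.C5: (7, 204)}
categories, truth = [], []
for cat, (b, m) in composition.items():
    categories += [cat] * (b + m)
    truth += [Histopathology.BENIGN] * b + [Histopathology.MALIGNANT] * m

cm = confusion_summary(categories, truth, scheme="statistical")
met = diagnostic_metrics(cm)
print(f"TP={cm.tp} FP={cm.fp} TN={cm.tn} FN={cm.fn}")
for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
    e = getattr(met, name)
    print(f"{name}: {percent_display(e.value)}% "
          f"(95% CI {percent_display(e.ci_low)}-{percent_display(e.ci_high)}%)")
```

prints

```
TP=346 FP=49 TN=281 FN=43
sensitivity: 89% (95% CI 85-92%)
specificity: 85% (95% CI 81-89%)
accuracy: 87% (95% CI 85-89%)
ppv: 88% (95% CI 84-90%)
npv: 87% (95% CI 83-90%)
```

Here 389 malignant and 330 benign nodes are binarized under the
statistical scheme (4b–5 positive), and each proportion gets a Wilson
95% interval. Under the management scheme (4a also referred for workup)
the same composition leaves only 2 missed malignancies.

The same pipeline from the shell:

```bash
lnrads simulate --seed 17 --output nodes.csv
lnrads classify --input nodes.csv --output classified.csv
lnrads evaluate --input classified.csv --scheme statistical --report report.md
lnrads thresholds --input nodes.csv --output panel.csv
```

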