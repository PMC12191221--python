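# Methods

## The rule cascade

Category assignment formalizes the published LN-RADS guideline text as a
deterministic, malignant-first cascade. For a validated record the
engine first collects the set *M* of high-risk features:

| id | predicate |
|---|---|
| `CTD_OVER_4B_WITH_IRREGULARITY` | CTD > 4 mm **and** cortex irregularity grade ≥ 3 |
| `FCT` | focal cortical thickening present |
| `NO_HILUM` | MTD = 0 |
| `ROUND` | SAD/LAD ≥ 0.5 (L/S ≤ 2) |
| `DEEP_HYPOECHOIC` | echogenicity grade ≥ 4 (near-anechoic "black hole") |
| `MICROCALCIFICATIONS`, `FLUID`, `NECROSIS` | the corresponding finding |
| `ABNORMAL_VASCULARITY` | Doppler pattern 4 (peripheral) or 5 (chaotic) |
| `BLURRED_MARGINS` | border grade ≥ 4 |

and then returns on the first matching rule: extracapsular infiltration
→ 5; enlarged SAD (> 9 mm) with ≥ 2 high-risk features → 5; any
high-risk feature → 4b; the benign screens for normal (1), steatotic (2)
and reactive (3) nodes; otherwise 4a. The 4a fallback mirrors the
guideline's negative definition of low-suspicion nodes ("better check
than miss"): category-3 morphology accompanied by any clinical flag
(oncological/hematological history, active regional neoplasm, rising
markers, other suspicious regional node, systemic symptoms) lands in 4a
and can never reach 4b/5 on clinical grounds alone.

Boundary conventions follow the guideline wording: "over X mm" is strict
(>), "maximum X mm" inclusive (≤). All cutoffs live in `RuleConfig`:
normal SAD ≤ 7 mm (the permissive end of the stated 6–7 mm), thin cortex
≤ 3 mm, 4b-level thickening > 4 mm, category-5-level thickening > 6 mm,
oval shape SAD/LAD < 0.5, category-5 enlargement SAD > 9 mm (the
ROC-optimal SAD cutoff rather than the conventional 10 mm), and "more
malignancy features" operationalized as a count ≥ 2. A missing Doppler
study is a first-class state: it satisfies the benign screens' vascular
clause and contributes nothing to *M* — it is never imputed.

The classifier is a pure function: identical record and configuration
always produce the identical category and rule trace.

## Diagnostic accuracy

Categories are binarized either *statistically* (4b–5 positive; 4a
counted with the benign side, as in the published accuracy figures) or
by *management* (4a–5 positive, since every 4a node is referred for
biopsy or PET). Sensitivity, specificity, accuracy, PPV and NPV are
plain binomial proportions; each gets a **Wilson score** 95% interval
(Clopper–Pearson available via `method="beta"`). The interval method is
a package choice — the study does not name one — and a known consequence
is that one printed bound is not reproduced: on the published counts the
specificity interval is [80.9%, 88.6%], whose upper bound rounds to 89
rather than the printed 88 (no standard interval on those counts rounds
to 88). Display rounding is half-up to integer percent; internal values
are never rounded. Metrics with zero denominators are reported as
undefined with a reason, never as 0 or 1.

Per-group malignancy risk is the malignant fraction with its Wilson
interval, computed for any grouping (categories, Doppler patterns).
Cohort-stratified sensitivity runs over records carrying a malignant
cohort tag (cancer, leukemia/lymphoma, melanoma/sarcoma, nonspecific).

## Per-feature threshold analysis

Each continuous feature is scored as a one-variable test with a
documented direction: LAD, SAD, CTD and SAD/LAD higher-is-malignant, the
medulla fraction MTD/(MTD + CTD) lower-is-malignant, the Doppler pattern
(over the Doppler-studied subset only) higher-is-malignant. Candidate
cutoffs are the distinct observed values — not midpoints — so
integer-millimetre thresholds arise naturally; positivity is
`value ≥ t` (or `≤ t` for lower-is-malignant). The operating point
maximizes the Youden index, with ties broken toward the least aggressive
cutoff (smallest under higher-is-malignant, largest under lower). AUC is
the rank/concordance statistic with tied benign–malignant pairs counted
1/2; its confidence interval uses the asymptotic variance of the
placement values (DeLong), computed from midranks. Curves are strictly
empirical — no binormal smoothing.

## Inter-rater agreement

Unweighted Cohen's kappa over the 6-category table,
κ = (p_o − p_e)/(1 − p_e), with the Fleiss–Cohen–Everitt large-sample
standard error and a Wald 95% interval clipped to [−1, 1]. Weighted
variants are deliberately absent: the conventional interpretation bands
(≤ 0 none, 0.01–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate,
0.61–0.80 substantial, 0.81–1.00 almost perfect) are stated for the
unweighted statistic. Degenerate marginals (p_e = 1) yield an explicit
"undefined" result. The implementation agrees with the direct
contingency-table formula on exhaustively enumerated small tables and
with an independent reference implementation to 1e-12.

## Synthetic cohorts

The generator exists so that every pipeline stage is testable without
clinical data. Its defaults are the published study conditions: group
sizes 330/233/93/48/17 (benign / cancer / leukemia–lymphoma /
melanoma–sarcoma / nonspecific), per-cohort means and SDs for LAD, SAD,
CTD and MTD in mm, benign and malignant Doppler-pattern mixtures
(8, 36, 11, 17, 7)/79 and (9, 15, 13, 60, 62)/159, and a Doppler-studied
fraction of 238/719.

Lengths are drawn from normals truncated below at zero and repaired to
the data-model ordering LAD ≥ SAD, CTD ≤ SAD, MTD ≤ SAD (cortex and
medulla are measured at different sites, so their *sum* is not bounded
by the short axis — indeed the published cohort means have
CTD + MTD > SAD for several cohorts). Truncation and repair both bias
sample means, so the generator calibrates: holding the quantile draws
fixed (common random numbers), it iterates each feature's latent
location until the post-repair sample means match the targets, a
monotone fixed point that converges in a few dozen cheap iterations and
keeps generation bytewise reproducible from the seed. Where a target is
the supremum of what the repair allows (melanoma/sarcoma CTD equals its
SAD target), the calibration approaches it from below, well within
sampling error at the default sizes. Final lengths are quantized to the
0.1 mm caliper resolution (half-up rounding is monotone, so ordering
survives), axes are floored at 0.1 mm, and MTD rounding to exactly 0
encodes an absent hilum, with `hilum_present` set to agree.

Subjective grades round a Gaussian latent N(1.6, 0.9) clipped to 1–5;
malignant nodes' latent shifts by `grade_shift` (default 1.5 grade
units) toward the malignant pole — a calibration choice, as no grade
distributions are published. Architectural-finding rates per outcome
class (e.g. FCT 25% malignant / 2% benign, extracapsular infiltration
4% / 0%) and clinical-flag rates (15% per flag in malignant groups, 2%
benign) are likewise package choices documented in
`lnrads.synthetic.DEFAULT_FINDING_RATES`; they are chosen once as
clinically plausible and are not fitted to anything.

Reader panels perturb a base category vector: each reader independently
keeps a category with probability 1 − p and otherwise steps one category
up or down (equal probability, clamped at the scale ends) — RADS
disagreements are predominantly adjacent-category. The implied kappa has
a closed form from the step kernel and the base distribution, which the
simulated panels recover within ±0.03 at n = 5000.

### What the generator does *not* emulate

Features are sampled independently within a group: no CTD–MTD or
SAD–LAD correlation is modelled, because only marginal moments are
published. Two visible consequences, worth keeping in mind when reading
synthetic-data results: (i) benign nodes frequently draw a "round"
SAD/LAD ≥ 0.5, so synthetic specificity (~0.25–0.30) is far below the
~0.85 a real cohort shows — synthetic checks of the classifier are
therefore directional (benign records reach categories 1–3 more often
than malignant ones; per-category risk is monotone), never absolute;
(ii) the medulla fraction becomes an unrealistically clean discriminator
(AUC ≈ 0.90 vs ≈ 0.87 for CTD), whereas on the real data CTD was the
single strongest predictor (0.894 vs 0.828) — the synthetic panel
preserves CTD's dominance over the size features LAD, SAD and SAD/LAD,
but not over the medulla fraction. The truncated-normal MTD model also
lacks an atom at zero, so absent hila are rarer in synthetic malignant
groups than in practice; malignancy still shows through low MTD values.

## Numerical and testing choices

Problem sizes are chosen to keep the whole suite fast while leaving
estimator noise well below the asserted tolerances: mean-recovery checks
use 2000–4000 records per group (tolerance two standard errors of the
target's SD), kappa recovery uses 5000 items (±0.03), oracle
equivalences (pairwise-concordance AUC, brute-force Youden scan,
contingency-table kappa, closed-form Wilson) are asserted to 1e-12 on
exhaustive or randomized small instances. Property tests run hypothesis
in derandomized mode. The CSV dialect is comma-separated UTF-8 with "."
decimals, booleans 0/1, empty cell = absent; lengths are accepted at
0.1 mm precision and never re-rounded internally.
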