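"""Synthetic lymph-node cohorts and multi-reader rating panels.

The generator emulates the statistical structure the evaluation pipeline
assumes, so every stage is testable without clinical data:

* Morphometric lengths (LAD, SAD, CTD, MTD, in mm) are drawn per cohort
  from zero-truncated normal distributions with the published per-cohort
  means and SDs, then repaired to respect the anatomical ordering
  LAD >= SAD, CTD <= SAD and MTD <= SAD. Both truncation and repair would bias
  the realized means away from their targets, so the generator runs a
  common-random-numbers fixed-point calibration: the latent location of
  each feature is iterated (with the quantile draws held fixed) until the
  post-repair sample means hit the targets. Where a target is
  unattainable under the ordering constraint (it is then the supremum of
  the reachable means), the calibration approaches it monotonically.
* MTD clipped to exactly 0 encodes an invisible hilum, and
  ``hilum_present`` is set accordingly.
* The vascular pattern is sampled, for a Doppler-studied fraction of
  nodes, from the published benign/malignant pattern mixtures.
* Subjective 1-5 grades come from a discretized Gaussian latent whose
  mean is shifted toward the malignant pole by ``grade_shift`` for
  malignant nodes.
* Reader panels perturb a base category vector with an adjacent-category
  (+/- 1 step, clamped at the ends) noise kernel — RADS disagreements
  are predominantly adjacent-category.

Everything is reproducible from the spec's seed: two runs with the same
spec yield identical records.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .domain import (
    ArchitecturalFindings,
    CATEGORY_ORDER,
    ClinicalContext,
    Cohort,
    Histopathology,
    LNRADSCategory,
    LymphNodeRecord,
    MorphometricFeatures,
    Region,
    SubjectiveGrades,
)
from .errors import ConfigError

__all__ = [
    "SyntheticCohortSpec",
    "generate_cohort",
    "generate_reader_panel",
    "DEFAULT_FEATURE_PARAMS",
    "DEFAULT_N_PER_GROUP",
    "DEFAULT_VASCULAR_MIXTURE",
]

GROUPS = ("benign", "cancer", "leukemia_lymphoma", "melanoma_sarcoma", "nonspecific")
_FEATURES = ("lad", "sad", "ctd", "mtd")

#: Published per-cohort (mean, sd) of each length in mm.
DEFAULT_FEATURE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "benign": {"lad": (17.2, 9.1), "sad": (7.4, 3.3), "ctd": (4.5, 3.2), "mtd": (2.9, 2.4)},
    "cancer": {"lad": (17.2, 10.0), "sad": (12.0, 7.7), "ctd": (11.5, 7.9), "mtd": (0.9, 1.8)},
    "leukemia_lymphoma": {"lad": (29.9, 11.7), "sad": (18.2, 7.6), "ctd": (15.4, 8.4), "mtd": (2.0, 2.5)},
    "melanoma_sarcoma": {"lad": (23.3, 14.7), "sad": (15.8, 11.6), "ctd": (15.8, 11.6), "mtd": (0.9, 1.9)},
    "nonspecific": {"lad": (16.6, 9.2), "sad": (10.0, 6.9), "ctd": (10.1, 7.1), "mtd": (1.1, 1.6)},
}

#: Published study group sizes (benign margin plus the four printed cohorts).
DEFAULT_N_PER_GROUP: dict[str, int] = {
    "benign": 330,
    "cancer": 233,
    "leukemia_lymphoma": 93,
    "melanoma_sarcoma": 48,
    "nonspecific": 17,
}

#: Empirical vascular-pattern mixtures (patterns 1..5) by outcome class.
DEFAULT_VASCULAR_MIXTURE: dict[str, tuple[float, ...]] = {
    "benign": tuple(np.array([8, 36, 11, 17, 7]) / 79.0),
    "malignant": tuple(np.array([9, 15, 13, 60, 62]) / 159.0),
}

#: Fraction of nodes studied with Color Doppler (238 of 719 in the study).
DEFAULT_DOPPLER_FRACTION = 238.0 / 719.0

#: Architectural-finding rates by outcome class. Not published as a table;
#: chosen once as clinically plausible (focal cortical thickening is the
#: common metastatic pattern, fluid/necrosis are late signs, benign nodes
#: almost never show any of these).
DEFAULT_FINDING_RATES: dict[str, dict[str, float]] = {
    "benign": {
        "fct": 0.02, "lct": 0.06, "microcalcifications": 0.01,
        "fluid_collections": 0.005, "necrosis": 0.005,
        "extracapsular_infiltration": 0.0, "steatotic_hilum": 0.3,
    },
    "malignant": {
        "fct": 0.25, "lct": 0.12, "microcalcifications": 0.08,
        "fluid_collections": 0.05, "necrosis": 0.07,
        "extracapsular_infiltration": 0.04, "steatotic_hilum": 0.02,
    },
}

DEFAULT_CLINICAL_FLAG_RATE: dict[str, float] = {
    "benign": 0.02,
    "cancer": 0.15,
    "leukemia_lymphoma": 0.15,
    "melanoma_sarcoma": 0.15,
    "nonspecific": 0.15,
}

_REGION_PROBS = np.array([243, 51, 278, 147]) / 719.0
_REGIONS = (Region.NECK, Region.PERICLAVICULAR, Region.AXILLA, Region.INGUINAL)

_GRADE_FIELDS = (
    "shape_grade",
    "cortex_irregularity_grade",
    "echogenicity_grade",
    "inhomogeneity_grade",
    "border_grade",
)


@dataclass
class SyntheticCohortSpec:
    """Generator parameters; defaults reproduce the study's structure."""

    n_per_group: dict[str, int] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    feature_params: dict[str, dict[str, tuple[float, float]]] = dataclass_field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_FEATURE_PARAMS.items()}
    )
    vascular_mixture: dict[str, Sequence[float]] = dataclass_field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_VASCULAR_MIXTURE.items()}
    )
    doppler_fraction: float = DEFAULT_DOPPLER_FRACTION
    #: latent-mean shift (in grade units) toward the malignant pole for
    #: malignant nodes' subjective grades
    grade_shift: float = 1.5
    clinical_flag_rate: dict[str, float] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_FLAG_RATE)
    )
    finding_rates: dict[str, dict[str, float]] = dataclass_field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_FINDING_RATES.items()}
    )
    #: benign-pole latent for subjective grades: grades round from
    #: N(grade_latent_mean, grade_latent_sd)
    grade_latent_mean: float = 1.6
    grade_latent_sd: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if self.n_per_group[g] < 0:
                raise ConfigError("group sizes must be >= 0")
        for cls, probs in self.vascular_mixture.items():
            p = np.asarray(probs, dtype=float)
            if p.size != 5 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"vascular mixture for {cls!r} must be 5 probabilities summing to 1"
                )
        if not 0.0 <= self.doppler_fraction <= 1.0:
            raise ConfigError("doppler_fraction must lie in [0, 1]")
        if self.grade_shift < 0:
            raise ConfigError("grade_shift must be >= 0")
        for g, (mean, sd) in (
            (g, mv) for g, fp in self.feature_params.items() for mv in fp.values()
        ):
            if mean <= 0 and sd > 0:
                raise ConfigError("feature means must be > 0")
            if sd < 0:
                raise ConfigError("feature sds must be >= 0")


def _truncnorm_ppf(u: np.ndarray, loc: float, sd: float) -> np.ndarray:
    """Inverse CDF of a normal(loc, sd) truncated below at 0."""
    phi0 = min(float(ndtr(-loc / sd)), 1.0 - 1e-12)
    return loc + sd * ndtri(phi0 + u * (1.0 - phi0))


def _truncnorm_mean(loc: float, sd: float) -> float:
    alpha = -loc / sd
    # mean of the lower-truncated normal: loc + sd * phi(a) / (1 - Phi(a));
    # norm.sf keeps the tail accurate for strongly negative locations
    return loc + sd * norm.pdf(alpha) / norm.sf(alpha)


def _initial_loc(target: float, sd: float) -> float:
    """Latent location whose zero-truncated mean equals *target*."""
    lo, hi = target - 4.0 * sd, target
    while _truncnorm_mean(lo, sd) > target and lo > target - 30.0 * sd:
        lo -= 2.0 * sd
    return brentq(lambda m: _truncnorm_mean(m, sd) - target, lo, hi, xtol=1e-10)


def _repair(lad, sad, ctd, mtd):
    """Impose the data-model ordering: LAD >= SAD, CTD <= SAD, MTD <= SAD.

    Cortex and medulla are measured at different sites of the node, so
    their sum is not constrained by the short axis (the published cohort
    means indeed have CTD + MTD exceeding SAD for several cohorts); each
    alone cannot exceed it.
    """
    sad = sad.copy()
    lad = np.maximum(lad, sad)
    ctd = np.minimum(ctd, sad)
    mtd = np.minimum(mtd, sad)
    return lad, sad, ctd, mtd


_CAL_ITERATIONS = 80
_CAL_TOL = 5e-4


def _calibrated_lengths(
    rng: np.random.Generator,
    params: Mapping[str, tuple[float, float]],
    n: int,
) -> dict[str, np.ndarray]:
    """Draw repaired LAD/SAD/CTD/MTD whose sample means match the targets.

    The quantile draws are fixed once; only the latent locations move, so
    the fixed-point iteration is deterministic and the post-repair means
    converge monotonically to the targets (or their supremum when the
    repair makes a target unattainable).
    """
    u = {f: rng.random(n) for f in _FEATURES}
    targets = {f: params[f][0] for f in _FEATURES}
    sds = {f: params[f][1] for f in _FEATURES}
    locs = {
        f: (targets[f] if sds[f] == 0 else _initial_loc(targets[f], sds[f]))
        for f in _FEATURES
    }

    def draw():
        raw = {
            f: (np.full(n, locs[f]) if sds[f] == 0 else _truncnorm_ppf(u[f], locs[f], sds[f]))
            for f in _FEATURES
        }
        lad, sad, ctd, mtd = _repair(raw["lad"], raw["sad"], raw["ctd"], raw["mtd"])
        return {"lad": lad, "sad": sad, "ctd": ctd, "mtd": mtd}

    for _ in range(_CAL_ITERATIONS):
        realized = draw()
        errs = {f: targets[f] - float(realized[f].mean()) for f in _FEATURES}
        if max(abs(e) for e in errs.values()) < _CAL_TOL:
            break
        for f in _FEATURES:
            if sds[f] > 0:
                # cap the shift: sup-limited targets would otherwise diverge
                locs[f] = min(locs[f] + errs[f], targets[f] + 8.0 * sds[f])
    out = draw()
    # 0.1 mm caliper quantization; half-up rounding is monotone, so the
    # pairwise order constraints survive it. Axes are floored at the
    # 0.1 mm resolution (a recorded axis cannot be 0).
    for f in _FEATURES:
        out[f] = np.round(out[f] + 1e-9, 1)
    out["sad"] = np.maximum(out["sad"], 0.1)
    out["lad"] = np.maximum(out["lad"], out["sad"])
    return out


def _sample_grades(
    rng: np.random.Generator, n: int, malignant: bool, spec: SyntheticCohortSpec
) -> dict[str, np.ndarray]:
    mu = spec.grade_latent_mean + (spec.grade_shift if malignant else 0.0)
    out = {}
    for name in _GRADE_FIELDS:
        latent = rng.normal(mu, spec.grade_latent_sd, n)
        out[name] = np.clip(np.rint(latent), 1, 5).astype(int)
    return out


def generate_cohort(spec: Optional[SyntheticCohortSpec] = None) -> list[LymphNodeRecord]:
    """Generate one synthetic cohort of lymph-node records.

    Records are grouped by cohort in a fixed order and fully reproducible
    from ``spec.seed``. Every record satisfies the data-model invariants
    (``validate_record`` returns no violations).
    """
    spec = spec if spec is not None else SyntheticCohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[LymphNodeRecord] = []
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        if n == 0:
            continue
        malignant = group != "benign"
        outcome_key = "malignant" if malignant else "benign"
        lengths = _calibrated_lengths(rng, spec.feature_params[group], n)
        grades = _sample_grades(rng, n, malignant, spec)

        hilum = lengths["mtd"] > 0.0
        rates = spec.finding_rates[outcome_key]
        draw = lambda p: rng.random(n) < p
        fct = draw(rates["fct"])
        lct = draw(rates["lct"])
        micro = draw(rates["microcalcifications"])
        fluid = draw(rates["fluid_collections"])
        necrosis = draw(rates["necrosis"])
        extracap = draw(rates["extracapsular_infiltration"])
        steatotic = hilum & draw(rates["steatotic_hilum"])

        doppler = rng.random(n) < spec.doppler_fraction
        mixture = np.asarray(spec.vascular_mixture[outcome_key], dtype=float)
        patterns = rng.choice(np.arange(1, 6), size=n, p=mixture / mixture.sum())

        flag_rate = spec.clinical_flag_rate[group]
        flags = {
            name: draw(flag_rate)
            for name in (
                "oncological_history",
                "hematological_history",
                "active_regional_neoplasm",
                "elevated_or_rising_markers",
                "other_suspicious_regional_ln",
                "systemic_symptoms",
            )
        }
        regions = rng.choice(len(_REGIONS), size=n, p=_REGION_PROBS)

        for i in range(n):
            records.append(
                LymphNodeRecord(
                    node_id=f"{group}-{i:05d}",
                    region=_REGIONS[regions[i]],
                    features=MorphometricFeatures(
                        sad_mm=float(lengths["sad"][i]),
                        lad_mm=float(lengths["lad"][i]),
                        ctd_mm=float(lengths["ctd"][i]),
                        mtd_mm=float(lengths["mtd"][i]),
                    ),
                    grades=SubjectiveGrades(
                        shape_grade=int(grades["shape_grade"][i]),
                        cortex_irregularity_grade=int(grades["cortex_irregularity_grade"][i]),
                        echogenicity_grade=int(grades["echogenicity_grade"][i]),
                        inhomogeneity_grade=int(grades["inhomogeneity_grade"][i]),
                        border_grade=int(grades["border_grade"][i]),
                        vascular_pattern=int(patterns[i]) if doppler[i] else None,
                    ),
                    findings=ArchitecturalFindings(
                        hilum_present=bool(hilum[i]),
                        steatotic_hilum=bool(steatotic[i]),
                        fct=bool(fct[i]),
                        lct=bool(lct[i]),
                        microcalcifications=bool(micro[i]),
                        fluid_collections=bool(fluid[i]),
                        necrosis=bool(necrosis[i]),
                        extracapsular_infiltration=bool(extracap[i]),
                    ),
                    clinical=ClinicalContext(
                        **{name: bool(v[i]) for name, v in flags.items()}
                    ),
                    histopathology=(
                        Histopathology.MALIGNANT if malignant else Histopathology.BENIGN
                    ),
                    cohort=Cohort(group),
                )
            )
    return records


def generate_reader_panel(
    base: Sequence[LNRADSCategory],
    n_readers: int,
    perturb_prob: float,
    seed: int,
) -> dict[str, list[LNRADSCategory]]:
    """Simulate readers re-rating a base category vector.

    Each reader independently keeps every base category with probability
    ``1 - perturb_prob`` and otherwise moves one step up or down the
    6-category order with equal probability, clamped at the ends (a step
    off the scale stays put).
    """
    if len(base) == 0:
        raise ValueError("base category vector must be non-empty")
    if not 0.0 <= perturb_prob <= 1.0:
        raise ValueError("perturb_prob must lie in [0, 1]")
    if n_readers < 1:
        raise ValueError("n_readers must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.array([c.rank for c in base])
    panel: dict[str, list[LNRADSCategory]] = {}
    for r in range(n_readers):
        name = string.ascii_uppercase[r] if r < 26 else f"R{r + 1}"
        perturb = rng.random(idx.size) < perturb_prob
        steps = rng.choice([-1, 1], size=idx.size)
        new_idx = np.where(perturb, np.clip(idx + steps, 0, 5), idx)
        panel[name] = [CATEGORY_ORDER[i] for i in new_idx]
    return panel
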