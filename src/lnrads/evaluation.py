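"""Diagnostic accuracy of assigned categories against histopathology.

Given per-node LN-RADS categories and benign/malignant truth, this
module builds the per-category confusion summary, the usual test
metrics (sensitivity, specificity, accuracy, PPV, NPV) with Wilson
score confidence intervals, per-group malignancy risk, and per-cohort
sensitivity under either binarization scheme.

Zero-denominator metrics are reported as undefined with a reason,
never fabricated as 0 or 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence, Union

from statsmodels.stats.proportion import proportion_confint

from .classifier import is_positive
from .domain import (
    CATEGORY_ORDER,
    Cohort,
    Histopathology,
    LNRADSCategory,
    MALIGNANT_COHORTS,
)
from .errors import MissingTruthError

__all__ = [
    "ConfusionSummary",
    "MetricEstimate",
    "DiagnosticMetrics",
    "GroupRisk",
    "confusion_summary",
    "diagnostic_metrics",
    "proportion_ci",
    "risk_by_group",
    "cohort_sensitivity",
    "percent_display",
]

TruthLike = Union[Histopathology, str]


def _as_truth(value: TruthLike, index: int) -> Histopathology:
    if isinstance(value, Histopathology):
        return value
    if value is None:
        raise MissingTruthError(f"record {index}: histopathology truth is missing")
    try:
        return Histopathology(str(value).strip().lower())
    except ValueError as exc:
        raise MissingTruthError(
            f"record {index}: truth must be 'benign' or 'malignant', got {value!r}"
        ) from exc


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-category benign/malignant counts plus scheme-binarized totals."""

    per_category: Mapping[LNRADSCategory, tuple[int, int]]  # (n_benign, n_malignant)
    scheme: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def misclassified(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion k/n with its confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    k: int
    n: int


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    accuracy: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    level: float
    #: metric name -> reason, for metrics whose denominator was zero
    undefined: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupRisk:
    n: int
    n_malignant: int
    proportion: float
    ci_low: float
    ci_high: float


def confusion_summary(
    categories: Sequence[LNRADSCategory],
    truth: Sequence[TruthLike],
    scheme: str = "statistical",
) -> ConfusionSummary:
    """Cross-tabulate categories against truth and binarize under *scheme*."""
    if len(categories) != len(truth):
        raise ValueError(
            f"length mismatch: {len(categories)} categories vs {len(truth)} truth labels"
        )
    counts = {cat: [0, 0] for cat in CATEGORY_ORDER}
    tp = fp = tn = fn = 0
    for i, (cat, t) in enumerate(zip(categories, truth)):
        outcome = _as_truth(t, i)
        malignant = outcome is Histopathology.MALIGNANT
        counts[cat][1 if malignant else 0] += 1
        positive = is_positive(cat, scheme)
        if positive and malignant:
            tp += 1
        elif positive:
            fp += 1
        elif malignant:
            fn += 1
        else:
            tn += 1
    per_category = {cat: (b, m) for cat, (b, m) in counts.items()}
    return ConfusionSummary(per_category=per_category, scheme=scheme, tp=tp, fp=fp, tn=tn, fn=fn)


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion k/n.

    The Wilson score interval is the default; ``method="beta"`` gives the
    Clopper-Pearson exact interval. Bounds are clipped to [0, 1] and
    always bracket k/n.
    """
    if n <= 0:
        raise ValueError("n must be > 0 for a proportion interval")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n]; got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    if method not in ("wilson", "beta"):
        raise ValueError(f"unknown interval method {method!r}")
    lo, hi = proportion_confint(count=k, nobs=n, alpha=1.0 - level, method=method)
    p = k / n
    return (min(max(float(lo), 0.0), p), max(min(float(hi), 1.0), p))


def _metric(
    k: int, n: int, level: float, method: str
) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    lo, hi = proportion_ci(k, n, level=level, method=method)
    return MetricEstimate(value=k / n, ci_low=lo, ci_high=hi, k=k, n=n)


def diagnostic_metrics(
    cm: ConfusionSummary, level: float = 0.95, method: str = "wilson"
) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, PPV and NPV with CIs from *cm*."""
    pieces = {
        "sensitivity": (cm.tp, cm.tp + cm.fn, "no records with malignant truth"),
        "specificity": (cm.tn, cm.tn + cm.fp, "no records with benign truth"),
        "accuracy": (cm.tp + cm.tn, cm.total, "no records"),
        "ppv": (cm.tp, cm.tp + cm.fp, "no test-positive records"),
        "npv": (cm.tn, cm.tn + cm.fn, "no test-negative records"),
    }
    estimates: dict[str, Optional[MetricEstimate]] = {}
    undefined: dict[str, str] = {}
    for name, (k, n, reason) in pieces.items():
        est = _metric(k, n, level, method)
        estimates[name] = est
        if est is None:
            undefined[name] = reason
    return DiagnosticMetrics(level=level, undefined=undefined, **estimates)


def risk_by_group(
    group_labels: Sequence,
    truth: Sequence[TruthLike],
    level: float = 0.95,
    method: str = "wilson",
) -> dict:
    """Malignant fraction (with Wilson CI) for each distinct group label."""
    if len(group_labels) != len(truth):
        raise ValueError("group_labels and truth must have equal lengths")
    tallies: dict = {}
    for i, (g, t) in enumerate(zip(group_labels, truth)):
        outcome = _as_truth(t, i)
        n, m = tallies.get(g, (0, 0))
        tallies[g] = (n + 1, m + (outcome is Histopathology.MALIGNANT))
    out = {}
    for g, (n, m) in tallies.items():
        lo, hi = proportion_ci(m, n, level=level, method=method)
        out[g] = GroupRisk(n=n, n_malignant=m, proportion=m / n, ci_low=lo, ci_high=hi)
    return out


def cohort_sensitivity(
    categories: Sequence[LNRADSCategory],
    truth: Sequence[TruthLike],
    cohorts: Sequence[Optional[Cohort]],
    scheme: str = "statistical",
    level: float = 0.95,
    method: str = "wilson",
) -> dict[Cohort, MetricEstimate]:
    """Per-neoplasm-cohort sensitivity under the given binarization scheme.

    Only records with a malignant cohort tag contribute; each must carry
    malignant truth. Raises on a tagged cohort with no malignant members.
    """
    if not (len(categories) == len(truth) == len(cohorts)):
        raise ValueError("categories, truth and cohorts must have equal lengths")
    members: dict[Cohort, list[int]] = {}
    for i, cohort in enumerate(cohorts):
        if cohort is None or cohort not in MALIGNANT_COHORTS:
            continue
        members.setdefault(cohort, []).append(i)
    out: dict[Cohort, MetricEstimate] = {}
    for cohort, idx in members.items():
        positives = 0
        n_malignant = 0
        for i in idx:
            if _as_truth(truth[i], i) is not Histopathology.MALIGNANT:
                raise MissingTruthError(
                    f"record {i}: cohort {cohort.value} requires malignant truth"
                )
            n_malignant += 1
            positives += is_positive(categories[i], scheme)
        if n_malignant == 0:
            raise ValueError(f"cohort {cohort.value} is empty")
        lo, hi = proportion_ci(positives, n_malignant, level=level, method=method)
        out[cohort] = MetricEstimate(
            value=positives / n_malignant, ci_low=lo, ci_high=hi,
            k=positives, n=n_malignant,
        )
    if not out:
        raise ValueError("no records carry a malignant cohort tag")
    return out


def percent_display(value: float) -> int:
    """Half-up rounding of a proportion to integer percent, for report display.

    Internal values are never rounded; this is the display convention only.
    """
    return int(
        Decimal(value * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
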