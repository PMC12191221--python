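"""Per-feature discrimination analysis: ROC, AUC and Youden-optimal cutoffs.

Every continuous morphometric feature is scored as a one-variable
diagnostic test. Curves are strictly empirical: candidate thresholds are
the distinct observed values (which is how integer-millimetre cutoffs
such as 9 mm for SAD arise naturally), the positivity rule is
``value >= threshold`` for higher-is-malignant features and
``value <= threshold`` for lower-is-malignant ones, AUC is the rank
(concordance) statistic with tied benign-malignant pairs counted 1/2,
and its confidence interval comes from the asymptotic covariance of the
paired concordance placements (DeLong). The operating threshold
maximizes the Youden index J = sensitivity + specificity - 1; ties are
broken toward the smallest threshold under higher-is-malignant and the
largest under lower-is-malignant, so the least aggressive cutoff with
maximal J is reported.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .domain import Histopathology, LymphNodeRecord, derive_ratios
from .errors import MissingTruthError, SingleClassError

__all__ = [
    "HIGHER_IS_MALIGNANT",
    "LOWER_IS_MALIGNANT",
    "ROCPoint",
    "AUCResult",
    "ThresholdResult",
    "roc_points",
    "auc",
    "youden_optimal",
    "feature_panel",
    "PANEL_FEATURES",
]

HIGHER_IS_MALIGNANT = "higher_is_malignant"
LOWER_IS_MALIGNANT = "lower_is_malignant"


class ROCPoint(NamedTuple):
    fpr: float
    tpr: float
    threshold: float


class AUCResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ThresholdResult:
    """One row of the per-feature metric panel."""

    feature_name: str
    direction: str
    threshold: float
    youden_j: float
    auc: AUCResult
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: Optional[float]
    npv: Optional[float]
    n_benign: int
    n_malignant: int


def _prepare(values, truth, direction):
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-d sequence")
    if len(truth) != v.size:
        raise ValueError("values and truth must have equal lengths")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if direction not in (HIGHER_IS_MALIGNANT, LOWER_IS_MALIGNANT):
        raise ValueError(f"unknown direction {direction!r}")
    y = np.array(
        [
            (t if isinstance(t, Histopathology) else Histopathology(str(t).strip().lower()))
            is Histopathology.MALIGNANT
            for t in truth
        ],
        dtype=bool,
    )
    if y.all() or not y.any():
        raise SingleClassError(
            "ROC analysis requires at least one benign and one malignant record"
        )
    return v, y


def roc_points(values, truth, direction: str = HIGHER_IS_MALIGNANT) -> list[ROCPoint]:
    """Empirical ROC curve: the (0, 0) endpoint plus one point per distinct
    observed value, ending at (1, 1).

    Under the ``>=``/``<=`` positivity rule the most permissive candidate
    threshold already yields (1, 1), so that endpoint is the final
    value-point; (0, 0) is emitted with an infinite threshold.
    """
    v, y = _prepare(values, truth, direction)
    sign = 1.0 if direction == HIGHER_IS_MALIGNANT else -1.0
    s = sign * v
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    points = [ROCPoint(0.0, 0.0, sign * math.inf)]
    tp = fp = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += bool(y_sorted[j])
            fp += not y_sorted[j]
            j += 1
        points.append(ROCPoint(fp / n_neg, tp / n_pos, sign * s_sorted[i]))
        i = j
    if points[-1][:2] != (1.0, 1.0):  # unreachable under the >= rule; kept defensive
        points.append(ROCPoint(1.0, 1.0, -sign * math.inf))
    return points


def auc(values, truth, direction: str = HIGHER_IS_MALIGNANT) -> AUCResult:
    """Concordance AUC with a DeLong-style asymptotic confidence interval.

    The estimate is the Mann-Whitney statistic (ties weighted 1/2),
    computed from midranks. The variance combines the sample variances of
    the per-positive and per-negative placement values.
    """
    v, y = _prepare(values, truth, direction)
    s = v if direction == HIGHER_IS_MALIGNANT else -v
    pos = s[y]
    neg = s[~y]
    n_pos, n_neg = pos.size, neg.size
    ranks = rankdata(s)
    estimate = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Placement values via midranks (Sun & Xu decomposition): avoids the
    # O(n_pos * n_neg) pairwise matrix.
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    v10 = (ranks[y] - ranks_pos) / n_neg          # per-positive placements
    v01 = 1.0 - (ranks[~y] - ranks_neg) / n_pos   # per-negative placements
    var = 0.0
    if n_pos > 1:
        var += np.var(v10, ddof=1) / n_pos
    if n_neg > 1:
        var += np.var(v01, ddof=1) / n_neg
    se = math.sqrt(var)
    z = norm.ppf(0.975)
    lo = min(max(estimate - z * se, 0.0), estimate)
    hi = max(min(estimate + z * se, 1.0), estimate)
    return AUCResult(float(estimate), float(lo), float(hi))


def youden_optimal(
    values,
    truth,
    direction: str = HIGHER_IS_MALIGNANT,
    feature_name: str = "",
) -> ThresholdResult:
    """Scan every distinct observed value as a cutoff and return the full
    metric panel at the Youden-optimal one."""
    v, y = _prepare(values, truth, direction)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    candidates = np.unique(v)
    if direction == HIGHER_IS_MALIGNANT:
        scan = candidates            # ascending: first argmax = smallest threshold
    else:
        scan = candidates[::-1]      # descending: first argmax = largest threshold
    best = None
    for thr in scan:
        positive = v >= thr if direction == HIGHER_IS_MALIGNANT else v <= thr
        tp = int(np.sum(positive & y))
        fp = int(np.sum(positive & ~y))
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(thr), tp, fp)
    j, thr, tp, fp = best
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    return ThresholdResult(
        feature_name=feature_name,
        direction=direction,
        threshold=thr,
        youden_j=j,
        auc=auc(values, truth, direction),
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / (n_pos + n_neg),
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
        n_benign=n_neg,
        n_malignant=n_pos,
    )


#: Panel features: name, extractor, direction, skip-predicate description.
PANEL_FEATURES = (
    ("LAD", HIGHER_IS_MALIGNANT),
    ("SAD", HIGHER_IS_MALIGNANT),
    ("CTD", HIGHER_IS_MALIGNANT),
    ("S/L ratio", HIGHER_IS_MALIGNANT),
    ("MTD/(MTD + CTD) ratio", LOWER_IS_MALIGNANT),
    ("vascular pattern", HIGHER_IS_MALIGNANT),
)


def _feature_values(records: Sequence[LymphNodeRecord], name: str):
    """Per-feature values and truth labels, skipping records where the
    feature is undefined (no Doppler; zero cortex-plus-medulla)."""
    vals, truth = [], []
    for r in records:
        if r.histopathology is None:
            raise MissingTruthError(
                f"record {r.node_id}: feature panel requires histopathology truth"
            )
        f = r.features
        if name == "LAD":
            x = f.lad_mm
        elif name == "SAD":
            x = f.sad_mm
        elif name == "CTD":
            x = f.ctd_mm
        elif name == "S/L ratio":
            x = f.sad_mm / f.lad_mm
        elif name == "MTD/(MTD + CTD) ratio":
            if f.ctd_mm + f.mtd_mm <= 0:
                continue
            x = derive_ratios(f).medulla_fraction
        elif name == "vascular pattern":
            if r.grades.vascular_pattern is None:
                continue
            x = float(r.grades.vascular_pattern)
        else:  # pragma: no cover
            raise ValueError(f"unknown panel feature {name!r}")
        vals.append(x)
        truth.append(r.histopathology)
    return vals, truth


def feature_panel(records: Sequence[LymphNodeRecord]) -> list[ThresholdResult]:
    """Youden analysis of every continuous feature, Table-style.

    LAD, SAD, CTD and S/L are analyzed higher-is-malignant; the medulla
    fraction MTD/(MTD + CTD) lower-is-malignant; the vascular pattern
    only over the Doppler-studied subset. Single-class errors propagate.
    """
    results = []
    for name, direction in PANEL_FEATURES:
        vals, truth = _feature_values(records, name)
        if not vals:  # e.g. no Doppler studies at all: feature not analyzable
            continue
        results.append(youden_optimal(vals, truth, direction, feature_name=name))
    return results
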