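"""ROC curves, AUC with CI, Youden-optimal cutoffs, and the feature panel."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnrads.domain import Histopathology
from lnrads.errors import MissingTruthError, SingleClassError
from lnrads.thresholds import (
    HIGHER_IS_MALIGNANT,
    LOWER_IS_MALIGNANT,
    auc,
    feature_panel,
    roc_points,
    youden_optimal,
)

from conftest import make_record

B, M = Histopathology.BENIGN, Histopathology.MALIGNANT


def auc_pairwise_oracle(values, truth, direction=HIGHER_IS_MALIGNANT):
    """Exhaustive benign-malignant pair enumeration, ties counted 1/2."""
    sign = 1.0 if direction == HIGHER_IS_MALIGNANT else -1.0
    pos = [sign * v for v, t in zip(values, truth) if t is M]
    neg = [sign * v for v, t in zip(values, truth) if t is B]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(values, truth, direction=HIGHER_IS_MALIGNANT):
    """Scan every distinct value; return (best J, tie-broken threshold)."""
    best_j, best_thr = -2.0, None
    candidates = sorted(set(values))
    if direction == LOWER_IS_MALIGNANT:
        candidates = candidates[::-1]
    for thr in candidates:
        tp = fp = 0
        npos = nneg = 0
        for v, t in zip(values, truth):
            positive = v >= thr if direction == HIGHER_IS_MALIGNANT else v <= thr
            if t is M:
                npos += 1
                tp += positive
            else:
                nneg += 1
                fp += positive
        j = tp / npos + (nneg - fp) / nneg - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return best_j, best_thr


# --- roc_points ---------------------------------------------------------------

def test_roc_passes_through_perfect_corner_when_separated():
    values = [1, 2, 3, 10, 11, 12]
    truth = [B, B, B, M, M, M]
    points = roc_points(values, truth)
    assert (0.0, 1.0) in {(p.fpr, p.tpr) for p in points}
    assert points[0][:2] == (0.0, 0.0)
    assert points[-1][:2] == (1.0, 1.0)


def test_roc_identical_values_is_diagonal():
    points = roc_points([5, 5, 5, 5], [B, M, B, M])
    assert [(p.fpr, p.tpr) for p in points] == [(0.0, 0.0), (1.0, 1.0)]


def test_roc_example_matches_bruteforce_enumeration():
    values = [0.1, 0.4, 0.35, 0.8]
    truth = [B, B, M, M]
    points = roc_points(values, truth)
    assert len(points) == 5  # (0,0) plus one point per distinct value
    # brute force: for each cutoff t, positive iff value >= t
    expected = {(0.0, 0.0)}
    for t in values:
        fpr = sum(v >= t for v, y in zip(values, truth) if y is B) / 2
        tpr = sum(v >= t for v, y in zip(values, truth) if y is M) / 2
        expected.add((fpr, tpr))
    assert {(p.fpr, p.tpr) for p in points} == expected
    fprs = [p.fpr for p in points]
    tprs = [p.tpr for p in points]
    assert fprs == sorted(fprs) and tprs == sorted(tprs)


def test_roc_single_class_errors():
    with pytest.raises(SingleClassError):
        roc_points([1, 2], [B, B])


# --- auc ----------------------------------------------------------------------

def test_auc_perfect_separation():
    assert auc([1, 2, 8, 9], [B, B, M, M]).estimate == 1.0


def test_auc_worked_example():
    res = auc([0.1, 0.4, 0.35, 0.8], [B, B, M, M])
    assert res.estimate == pytest.approx(0.75)  # 3 of 4 concordant pairs
    assert res.ci_low <= res.estimate <= res.ci_high


def test_auc_null_behaviour_on_permuted_labels():
    rng = np.random.default_rng(3)
    values = rng.normal(size=4000)
    truth = [M if rng.random() < 0.5 else B for _ in values]
    est = auc(values, truth).estimate
    assert abs(est - 0.5) < 0.03


@settings(max_examples=100, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 8), st.booleans()), min_size=4, max_size=50
    ).filter(lambda d: 0 < sum(t for _, t in d) < len(d)),
    direction=st.sampled_from([HIGHER_IS_MALIGNANT, LOWER_IS_MALIGNANT]),
)
def test_auc_equals_pairwise_oracle(data, direction):
    """Rank-statistic AUC equals exhaustive pair enumeration (with ties)."""
    values = [v for v, _ in data]
    truth = [M if t else B for _, t in data]
    res = auc(values, truth, direction)
    assert res.estimate == pytest.approx(auc_pairwise_oracle(values, truth, direction), abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.floats(-5, 5), st.booleans()), min_size=4, max_size=40
    ).filter(lambda d: 0 < sum(t for _, t in d) < len(d))
)
def test_auc_direction_inversion_symmetry(data):
    values = [v for v, _ in data]
    truth = [M if t else B for _, t in data]
    hi = auc(values, truth, HIGHER_IS_MALIGNANT).estimate
    lo = auc(values, truth, LOWER_IS_MALIGNANT).estimate
    assert hi == pytest.approx(1.0 - lo, abs=1e-12)


def test_auc_equals_trapezoid_under_roc_curve():
    rng = np.random.default_rng(11)
    values = np.round(rng.normal(size=200), 1)
    truth = [M if rng.random() < 0.4 + 0.1 * v else B for v in values]
    if all(t is M for t in truth) or all(t is B for t in truth):
        pytest.skip("degenerate draw")
    points = roc_points(values, truth)
    area = np.trapezoid([p.tpr for p in points], [p.fpr for p in points])
    assert auc(values, truth).estimate == pytest.approx(area, abs=1e-12)


def test_auc_ci_matches_sklearn_point_estimate():
    """Independent cross-check of the point estimate against scikit-learn."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    values = np.round(rng.normal(size=300), 1)
    labels = (rng.random(300) < 0.3 + 0.15 * (values > 0)).astype(int)
    truth = [M if y else B for y in labels]
    assert auc(values, truth).estimate == pytest.approx(
        roc_auc_score(labels, values), abs=1e-12
    )


# --- youden_optimal -----------------------------------------------------------

def test_youden_separated_classes():
    res = youden_optimal([4, 5, 6, 8, 9, 10], [B, B, B, M, M, M])
    assert res.threshold == 8
    assert res.youden_j == pytest.approx(1.0)
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_youden_uninformative_feature():
    res = youden_optimal([5, 5, 5, 5], [B, M, B, M])
    assert res.youden_j == pytest.approx(0.0)


def test_youden_tie_breaks_toward_smallest_threshold():
    res = youden_optimal([2, 9, 8, 15], [B, B, M, M])
    assert res.threshold == 8  # J = 0.5 at both 8 and 15; smallest wins
    assert res.sensitivity == 1.0
    assert res.specificity == 0.5
    assert res.youden_j == pytest.approx(0.5)


def test_youden_invariant_j_identity():
    rng = np.random.default_rng(9)
    values = rng.integers(0, 20, size=80)
    truth = [M if rng.random() < 0.5 else B for _ in values]
    res = youden_optimal(values, truth)
    assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1.0)


@settings(max_examples=100, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 10), st.booleans()), min_size=4, max_size=40
    ).filter(lambda d: 0 < sum(t for _, t in d) < len(d)),
    direction=st.sampled_from([HIGHER_IS_MALIGNANT, LOWER_IS_MALIGNANT]),
)
def test_youden_matches_bruteforce_scan(data, direction):
    values = [v for v, _ in data]
    truth = [M if t else B for _, t in data]
    res = youden_optimal(values, truth, direction)
    best_j, best_thr = youden_bruteforce(values, truth, direction)
    assert res.youden_j == pytest.approx(best_j, abs=1e-12)
    assert res.threshold == best_thr


# --- feature_panel ------------------------------------------------------------

def test_feature_panel_requires_truth():
    with pytest.raises(MissingTruthError):
        feature_panel([make_record()])


def test_feature_panel_single_class_cohort_errors():
    records = [
        make_record(node_id=str(i), histopathology=B, sad=4 + i, lad=10 + i)
        for i in range(5)
    ]
    with pytest.raises(SingleClassError):
        feature_panel(records)


def test_feature_panel_constructed_separation():
    """Malignant CTD shifted far above benign CTD gives AUC 1 for CTD."""
    records = [
        make_record(node_id=f"b{i}", sad=8, lad=20, ctd=2 + 0.1 * i, mtd=2, histopathology=B)
        for i in range(10)
    ] + [
        make_record(node_id=f"m{i}", sad=150, lad=200, ctd=102 + 0.1 * i, mtd=2,
                    histopathology=M)
        for i in range(10)
    ]
    panel = {r.feature_name: r for r in feature_panel(records)}
    assert panel["CTD"].auc.estimate == 1.0
    assert panel["CTD"].youden_j == pytest.approx(1.0)


def test_feature_panel_on_synthetic_cohort(default_cohort):
    """Directional check on the default synthetic cohort: cortical thickness
    dominates the size features, and the strong predictors (CTD and the
    medulla fraction) clearly discriminate."""
    panel = {r.feature_name: r for r in feature_panel(default_cohort)}
    assert set(panel) == {
        "LAD", "SAD", "CTD", "S/L ratio", "MTD/(MTD + CTD) ratio", "vascular pattern",
    }
    ctd = panel["CTD"].auc.estimate
    assert ctd > panel["LAD"].auc.estimate
    assert ctd > panel["SAD"].auc.estimate
    assert ctd > panel["S/L ratio"].auc.estimate
    assert ctd > 0.8
    assert panel["MTD/(MTD + CTD) ratio"].auc.estimate > 0.8
    assert panel["MTD/(MTD + CTD) ratio"].direction == LOWER_IS_MALIGNANT
    # Doppler-present subset only
    n_doppler = sum(r.grades.vascular_pattern is not None for r in default_cohort)
    vp = panel["vascular pattern"]
    assert vp.n_benign + vp.n_malignant == n_doppler
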