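"""Evaluation pipeline driver and markdown report generation."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .domain import CATEGORY_ORDER, Cohort, Histopathology, LNRADSCategory
from .classifier import is_positive
from .evaluation import (
    ConfusionSummary,
    DiagnosticMetrics,
    GroupRisk,
    MetricEstimate,
    cohort_sensitivity,
    confusion_summary,
    diagnostic_metrics,
    percent_display,
    risk_by_group,
)
from .io import RunConfig, rule_config_to_yaml

__all__ = ["EvaluationReport", "evaluate_categories", "render_report", "write_report"]


@dataclass(frozen=True)
class EvaluationReport:
    confusion: ConfusionSummary
    metrics: DiagnosticMetrics
    risk: dict[LNRADSCategory, GroupRisk]
    cohort_sens: Optional[dict[Cohort, MetricEstimate]]
    scheme: str
    level: float


def evaluate_categories(
    categories: Sequence[LNRADSCategory],
    truth: Sequence,
    cohorts: Optional[Sequence[Optional[Cohort]]] = None,
    scheme: str = "statistical",
    level: float = 0.95,
    method: str = "wilson",
) -> EvaluationReport:
    """Run the full evaluation stage on assigned categories vs truth."""
    cm = confusion_summary(categories, truth, scheme)
    metrics = diagnostic_metrics(cm, level=level, method=method)
    risk = risk_by_group(list(categories), list(truth), level=level, method=method)
    cohort_sens = None
    if cohorts is not None and any(c is not None for c in cohorts):
        cohort_sens = cohort_sensitivity(
            categories, truth, cohorts, scheme=scheme, level=level, method=method
        )
    return EvaluationReport(
        confusion=cm, metrics=metrics, risk=risk, cohort_sens=cohort_sens,
        scheme=scheme, level=level,
    )


def _pct(x: float) -> str:
    return f"{percent_display(x)}%"


def _metric_line(name: str, est: Optional[MetricEstimate], reason: str = "") -> str:
    if est is None:
        return f"- {name}: undefined ({reason})"
    return (
        f"- {name}: {_pct(est.value)} (95% CI {_pct(est.ci_low)}-{_pct(est.ci_high)})"
        f" [{est.k}/{est.n}]"
    )


def render_report(report: EvaluationReport, run_config: Optional[RunConfig] = None) -> str:
    """Markdown report: per-category counts, metric block, risk, cohorts,
    and the exact configuration used."""
    lines: list[str] = ["# LN-RADS evaluation report", ""]
    if report.confusion.total == 0:
        lines.append("no records")
        lines.append("")
    else:
        lines.append(f"Binarization scheme: **{report.scheme}**")
        lines.append("")
        lines.append("## Per-category outcome counts")
        lines.append("")
        lines.append("| Category | Benign | Malignant | Binarized |")
        lines.append("|---|---|---|---|")
        for cat in CATEGORY_ORDER:
            b, m = report.confusion.per_category[cat]
            side = "positive" if is_positive(cat, report.scheme) else "negative"
            lines.append(f"| LN-RADS {cat.value} | {b} | {m} | {side} |")
        cm = report.confusion
        lines.append("")
        lines.append("## Confusion totals")
        lines.append("")
        for name, value in (("TP", cm.tp), ("FP", cm.fp), ("TN", cm.tn), ("FN", cm.fn)):
            lines.append(f"- {name} {value}")
        lines.append(f"- misclassified {cm.misclassified} of {cm.total}")
        lines.append("")
        lines.append("## Diagnostic metrics")
        lines.append("")
        met = report.metrics
        for name, est in (
            ("sensitivity", met.sensitivity),
            ("specificity", met.specificity),
            ("accuracy", met.accuracy),
            ("PPV", met.ppv),
            ("NPV", met.npv),
        ):
            key = name.lower()
            lines.append(_metric_line(name, est, met.undefined.get(key, "")))
        lines.append("")
        lines.append("## Risk of malignancy by category")
        lines.append("")
        for cat in CATEGORY_ORDER:
            if cat in report.risk:
                g = report.risk[cat]
                lines.append(
                    f"- LN-RADS {cat.value}: {_pct(g.proportion)}"
                    f" ({g.n_malignant}/{g.n}, 95% CI {_pct(g.ci_low)}-{_pct(g.ci_high)})"
                )
        lines.append("")
        if report.cohort_sens:
            lines.append("## Sensitivity by neoplasm cohort")
            lines.append("")
            for cohort, est in sorted(report.cohort_sens.items(), key=lambda kv: kv[0].value):
                lines.append(_metric_line(cohort.value, est))
            lines.append("")
    if run_config is not None:
        lines.append("## Run configuration")
        lines.append("")
        lines.append(f"- scheme: {run_config.scheme}")
        lines.append(f"- ci_level: {run_config.ci_level}")
        lines.append(f"- seed: {run_config.seed}")
        lines.append("- rule thresholds:")
        lines.append("```yaml")
        lines.append(rule_config_to_yaml(run_config.rule_config).rstrip())
        lines.append("```")
        lines.append("")
    return "\n".join(lines)


def write_report(
    report: EvaluationReport,
    path: Union[str, Path],
    run_config: Optional[RunConfig] = None,
) -> None:
    Path(path).write_text(render_report(report, run_config), encoding="utf-8")
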