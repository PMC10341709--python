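"""Cohort analysis report: group-comparison table, diagnostic performance,
and the CSF CXCL13 vs TNC regression.

``run_analysis`` stratifies a cohort with the threshold policy, builds the
group-comparison summary (median [IQR] / mean (SD) / n (%) cells with
Kruskal–Wallis or Fisher p-values and significance marks), the per-outcome
confusion tables with exact confidence intervals, and the least-squares fit
of total nucleated cell count on CSF CXCL13.  ``render`` serialises the
report to markdown, TSV or JSON; every number in a rendered table is
produced by the corresponding library operation, never re-derived in the
renderer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from typing import Optional, Sequence

from . import __version__
from .cohort import PatientRecord, Sex
from .index import Basis, Group, IndexResult, ThresholdPolicy, DEFAULT_POLICY, stratify_cohort
from .metrics import (
    OUTCOME_LABELS,
    OUTCOMES,
    ConfusionTable,
    DiagnosticPerformance,
    build_confusion,
    diagnostic_performance,
    percent_mris_with_new_lesions,
)
from .stats import FitResult, SummaryRow, format_p, linear_fit_r2, summarize_variable

logger = logging.getLogger(__name__)

GROUP_ORDER = ("low", "high")


@dataclasses.dataclass(frozen=True)
class OutcomeSection:
    outcome: str
    label: str
    table: ConfusionTable
    performance: DiagnosticPerformance


@dataclasses.dataclass(frozen=True)
class AnalysisReport:
    n_records: int
    group_sizes: dict[str, int]
    n_indeterminate: int
    n_csf_only: int
    summary_rows: list[SummaryRow]
    confusion_sections: list[OutcomeSection]
    regression: Optional[FitResult]
    provenance: dict


def _policy_hash(policy: ThresholdPolicy) -> str:
    payload = json.dumps(policy.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _group_values(records, strata, extractor) -> dict[str, list]:
    out: dict[str, list] = {g: [] for g in GROUP_ORDER}
    for rec in records:
        group = strata[rec.patient_id].group
        if group is Group.INDETERMINATE:
            continue
        value = extractor(rec, strata[rec.patient_id])
        if value is not None:
            out[group.value].append(value)
    return out


def build_summary_rows(
    records: Sequence[PatientRecord],
    strata: dict[str, IndexResult],
) -> list[SummaryRow]:
    """Assemble the group-comparison rows in the standard cohort-table order."""

    def grouped(extractor):
        return _group_values(records, strata, extractor)

    def lesion_category(rec: PatientRecord, _res) -> str:
        if rec.outcomes.n_mris == 0:
            return "No MRIs Performed"
        if rec.outcomes.n_mris_with_new_lesions == 0:
            return "None"
        if rec.outcomes.n_mris_with_new_lesions == 1:
            return "One"
        return "More than one"

    rows = [
        summarize_variable(
            "I_CXCL13 (median [IQR])",
            grouped(lambda r, res: res.index if res.index is not None else float("nan")),
            "continuous_median_iqr",
        ),
        summarize_variable(
            "Serum available (%)",
            grouped(lambda r, res: r.analytes.serum_cxcl13 is not None),
            "binary",
        ),
        summarize_variable(
            "CSF CXCL13 (pg/mL) (median [IQR])",
            grouped(lambda r, res: r.analytes.csf_cxcl13),
            "continuous_median_iqr",
        ),
        summarize_variable(
            "Age (mean (SD))",
            grouped(lambda r, res: r.age),
            "continuous_mean_sd",
        ),
        summarize_variable(
            "Sex = male (%)",
            grouped(lambda r, res: r.sex is Sex.MALE if r.sex is not Sex.OTHER else None),
            "binary",
        ),
        summarize_variable(
            "Diagnosis (%)",
            grouped(lambda r, res: r.diagnosis.value),
            "categorical",
        ),
        summarize_variable(
            "Follow Up Years (median [IQR])",
            grouped(lambda r, res: r.outcomes.followup_years),
            "continuous_median_iqr",
        ),
        summarize_variable(
            "Converted to CDMS (%)",
            grouped(lambda r, res: r.outcomes.converted_cdms),
            "binary",
        ),
        summarize_variable(
            "OCB Positive (%)",
            grouped(lambda r, res: r.outcomes.ocb_positive),
            "binary",
        ),
        summarize_variable(
            "One or more clinical attacks (%)",
            grouped(lambda r, res: r.outcomes.n_attacks >= 1),
            "binary",
        ),
        summarize_variable(
            "Number of MRIs during follow-up (median [IQR])",
            grouped(lambda r, res: float(r.outcomes.n_mris)),
            "continuous_median_iqr",
        ),
        summarize_variable(
            "Number of MRIs with new lesions (%)",
            grouped(lesion_category),
            "categorical",
        ),
        summarize_variable(
            "Number of New or Enhancing Lesions (mean (SD))",
            grouped(lambda r, res: float(r.outcomes.n_new_or_enhancing_lesions)),
            "continuous_mean_sd",
        ),
        summarize_variable(
            "Percent of MRIs with new lesions (%) (median [IQR])",
            grouped(
                lambda r, res: (
                    100.0 * p if (p := percent_mris_with_new_lesions(r)) is not None else None
                )
            ),
            "continuous_median_iqr",
        ),
        summarize_variable(
            "Treatment (%)",
            grouped(lambda r, res: r.treatment),
            "categorical",
        ),
    ]
    return rows


def run_analysis(
    records: Sequence[PatientRecord],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> AnalysisReport:
    """Full deterministic analysis of a validated cohort."""
    strata = stratify_cohort(records, policy)
    sizes = {g: 0 for g in ("high", "low", "indeterminate")}
    n_csf_only = 0
    for res in strata.values():
        sizes[res.group.value] += 1
        n_csf_only += res.basis is Basis.CSF_ONLY
    logger.info(
        "stratified %d records: %d high / %d low / %d indeterminate (%d CSF-only)",
        len(records), sizes["high"], sizes["low"], sizes["indeterminate"], n_csf_only,
    )

    summary_rows = build_summary_rows(records, strata)

    sections = []
    for outcome in OUTCOMES:
        table = build_confusion(records, strata, outcome)
        sections.append(
            OutcomeSection(
                outcome=outcome,
                label=OUTCOME_LABELS[outcome],
                table=table,
                performance=diagnostic_performance(table),
            )
        )
    logger.info("confusion tables built for %d outcomes", len(sections))

    regression = None
    xs = [r.analytes.csf_cxcl13 for r in records if r.analytes.tnc is not None]
    ys = [r.analytes.tnc for r in records if r.analytes.tnc is not None]
    if len(xs) >= 3 and len(set(xs)) > 1:
        regression = linear_fit_r2(xs, ys)
        logger.info("TNC regression: n=%d R²=%.3f", regression.n, regression.r_squared)

    return AnalysisReport(
        n_records=len(records),
        group_sizes={g: sizes[g] for g in ("low", "high")},
        n_indeterminate=sizes["indeterminate"],
        n_csf_only=n_csf_only,
        summary_rows=summary_rows,
        confusion_sections=sections,
        regression=regression,
        provenance={
            "policy": policy.model_dump(),
            "policy_hash": _policy_hash(policy),
            "software_version": __version__,
            "n_records": len(records),
        },
    )


# --- rendering ---------------------------------------------------------------

def _fmt_ci(est) -> str:
    if not est.defined:
        return "NA"
    return f"{est.value:.2f} ({est.ci_low:.2f}–{est.ci_high:.2f})"


def _summary_table_rows(report: AnalysisReport) -> list[tuple[str, str, str, str, str]]:
    rows = [("n", str(report.group_sizes["low"]), str(report.group_sizes["high"]), "", "")]
    for row in report.summary_rows:
        if row.levels:
            rows.append((row.variable, "", "", "", ""))
            for level, cells in row.levels.items():
                rows.append((f"  {level}", cells["low"], cells["high"], "", ""))
        else:
            rows.append(
                (row.variable, row.cells["low"], row.cells["high"], row.p_formatted, row.significance)
            )
    return rows


def render(report: AnalysisReport, format: str) -> str:
    """Serialise a report to ``markdown``, ``tsv`` or ``json``."""
    if format == "json":
        return json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True)
    if format == "markdown":
        lines = ["# Cohort analysis", ""]
        lines += [
            f"Records: {report.n_records} "
            f"({report.group_sizes['high']} high / {report.group_sizes['low']} low / "
            f"{report.n_indeterminate} indeterminate; {report.n_csf_only} classified CSF-only; "
            "indeterminate patients excluded from all comparisons)",
            "",
            "## Group comparison",
            "",
            "| Variable | Low | High | p-Value | |",
            "| --- | --- | --- | --- | --- |",
        ]
        for cells in _summary_table_rows(report):
            lines.append("| " + " | ".join(cells) + " |")
        lines += [
            "",
            "## Diagnostic performance of the stratification",
            "",
            "| Outcome | Sensitivity | Specificity | TP | FP | TN | FN |",
            "| --- | --- | --- | --- | --- | --- | --- |",
        ]
        for sec in report.confusion_sections:
            t = sec.table
            lines.append(
                f"| {sec.label} | {_fmt_ci(sec.performance.sensitivity)} | "
                f"{_fmt_ci(sec.performance.specificity)} | {t.tp} | {t.fp} | {t.tn} | {t.fn} |"
            )
        lines.append("")
        if report.regression is not None:
            r = report.regression
            lines += [
                "## CSF CXCL13 vs total nucleated cell count",
                "",
                f"OLS slope {r.slope:.3f} (p = {format_p(r.p_value_slope)}), "
                f"R² = {r.r_squared:.2f}, n = {r.n}",
                "",
            ]
        lines.append(
            f"Provenance: policy {report.provenance['policy_hash']}, "
            f"version {report.provenance['software_version']}"
        )
        return "\n".join(lines) + "\n"
    if format == "tsv":
        lines = ["section\tvariable\tlow\thigh\tp_value\tsignificance"]
        for cells in _summary_table_rows(report):
            lines.append("summary\t" + "\t".join(cells))
        lines.append(
            "section\toutcome\tsensitivity\tsens_ci_low\tsens_ci_high"
            "\tspecificity\tspec_ci_low\tspec_ci_high\ttp\tfp\ttn\tfn"
        )

        def num(v) -> str:
            return "NA" if v is None else f"{v:.6g}"

        for sec in report.confusion_sections:
            p = sec.performance
            t = sec.table
            lines.append(
                "confusion\t" + "\t".join(
                    [
                        sec.label,
                        num(p.sensitivity.value), num(p.sensitivity.ci_low), num(p.sensitivity.ci_high),
                        num(p.specificity.value), num(p.specificity.ci_low), num(p.specificity.ci_high),
                        str(t.tp), str(t.fp), str(t.tn), str(t.fn),
                    ]
                )
            )
        if report.regression is not None:
            r = report.regression
            lines.append(
                f"regression\ttnc_vs_csf_cxcl13\t{r.slope:.6g}\t{r.intercept:.6g}"
                f"\t{r.r_squared:.6g}\t{r.p_value_slope:.6g}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}; expected markdown, tsv or json")
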