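"""Binary outcome derivation, 2x2 confusion tables and diagnostic performance.

A positive "test" is membership in the index-high group; a negative test is
the index-low group; indeterminate patients are excluded.  Outcomes are
CDMS conversion, one or more clinical attacks, and one or more MRIs showing
new lesions over follow-up.  Patients with no surveillance MRIs count as
negative for the lesion outcome.  Sensitivity/specificity/PPV/NPV carry
exact (Clopper–Pearson) 95% confidence intervals; a zero denominator yields
a flagged-undefined estimate rather than a propagated NaN.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .cohort import PatientRecord
from .index import Group, IndexResult

OUTCOMES = ("cdms", "attacks", "new_lesions")

OUTCOME_LABELS = {
    "cdms": "Converted to CDMS",
    "new_lesions": "One or more new lesions",
    "attacks": "One or more clinical attacks",
}


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def transpose(self) -> "ConfusionTable":
        """Swap tp<->tn and fp<->fn (relabels both test and outcome)."""
        return ConfusionTable(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclasses.dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with an exact two-sided 95% CI.

    ``defined`` is False (and the numbers None) when the denominator is 0.
    """

    numerator: int
    denominator: int
    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclasses.dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate


def outcome_predicate(record: PatientRecord, outcome: str) -> bool:
    """Evaluate one of the binary outcome definitions on a record."""
    if outcome == "cdms":
        return record.outcomes.converted_cdms
    if outcome == "attacks":
        return record.outcomes.n_attacks >= 1
    if outcome == "new_lesions":
        # zero-MRI patients are outcome-negative by definition
        return record.outcomes.n_mris_with_new_lesions >= 1
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


def build_confusion(
    records: Sequence[PatientRecord],
    strata: Mapping[str, IndexResult],
    outcome: str,
) -> ConfusionTable:
    """Cross-classify group (high=positive, low=negative) against an outcome.

    Indeterminate patients are excluded; every record must have a stratum.
    """
    tp = fp = tn = fn = 0
    for rec in records:
        if rec.patient_id not in strata:
            raise KeyError(f"no stratum for patient {rec.patient_id!r}")
        group = strata[rec.patient_id].group
        if group is Group.INDETERMINATE:
            continue
        positive = outcome_predicate(rec, outcome)
        if group is Group.HIGH:
            tp += positive
            fp += not positive
        else:
            fn += positive
            tn += not positive
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


def _proportion(numerator: int, denominator: int) -> ProportionEstimate:
    if denominator == 0:
        return ProportionEstimate(numerator, denominator, None, None, None)
    low, high = proportion_confint(numerator, denominator, alpha=0.05, method="beta")
    return ProportionEstimate(numerator, denominator, numerator / denominator, float(low), float(high))


def diagnostic_performance(table: ConfusionTable) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV and NPV with Clopper–Pearson 95% CIs."""
    return DiagnosticPerformance(
        sensitivity=_proportion(table.tp, table.tp + table.fn),
        specificity=_proportion(table.tn, table.tn + table.fp),
        ppv=_proportion(table.tp, table.tp + table.fp),
        npv=_proportion(table.tn, table.tn + table.fn),
    )


def percent_mris_with_new_lesions(record: PatientRecord) -> Optional[float]:
    """Fraction of surveillance MRIs showing a new lesion, in [0, 1].

    The screening-adjusted activity measure: undefined (None) for patients
    with no MRIs, who are excluded from group medians of this quantity.
    """
    if record.outcomes.n_mris == 0:
        return None
    return record.outcomes.n_mris_with_new_lesions / record.outcomes.n_mris
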