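"""CXCL13 quotients, the intrathecal-synthesis index, and group assignment.

The CXCL13 index corrects the CSF/serum CXCL13 ratio for blood–CSF barrier
permeability using the albumin quotient:

    Q_CXCL13 = CXCL13_CSF / CXCL13_serum
    Q_albumin = albumin_CSF / albumin_serum
    I_CXCL13 = Q_CXCL13 / Q_albumin

Patients are stratified into high / low / indeterminate groups.  When the
index is computable it is compared against the index cuts (default: high
above 30, low below 20).  When serum CXCL13 is unavailable the CSF
concentration alone is used with harmonized cuts (high above 14 pg/mL, low
below 5 pg/mL) — in the motivating series an elevated index was never seen
below 5 pg/mL and always seen above 14 pg/mL.  Values exactly on a cut, or
between the cuts, are indeterminate.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import AnalytePanel, PatientRecord


class Group(str, enum.Enum):
    HIGH = "high"
    LOW = "low"
    INDETERMINATE = "indeterminate"


class Basis(str, enum.Enum):
    INDEX = "index"
    CSF_ONLY = "csf_only"


class ThresholdPolicy(BaseModel):
    """Classification cuts for the two threshold systems.

    ``index_high_cut``/``index_low_cut`` apply to the dimensionless index;
    ``csf_high_cut``/``csf_low_cut`` (pg/mL) apply to CSF CXCL13 when serum
    is unavailable.  Defaults are the cuts fixed in the motivating studies.
    """

    model_config = ConfigDict(frozen=True)

    index_high_cut: float = Field(default=30.0, gt=0)
    index_low_cut: float = Field(default=20.0, gt=0)
    csf_high_cut: float = Field(default=14.0, gt=0)
    csf_low_cut: float = Field(default=5.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdPolicy":
        if not self.index_low_cut < self.index_high_cut:
            raise ValueError("index_low_cut must be below index_high_cut")
        if not self.csf_low_cut < self.csf_high_cut:
            raise ValueError("csf_low_cut must be below csf_high_cut")
        return self


@dataclasses.dataclass(frozen=True)
class IndexResult:
    """Quotients, index and (once classified) group assignment for one patient."""

    q_cxcl13: Optional[float] = None
    q_albumin: Optional[float] = None
    index: Optional[float] = None
    group: Optional[Group] = None
    basis: Optional[Basis] = None


DEFAULT_POLICY = ThresholdPolicy()


def compute_index(panel: AnalytePanel) -> IndexResult:
    """Compute Q_CXCL13, Q_albumin and the index from an analyte panel.

    Each quantity is populated exactly when its inputs are present; no group
    is assigned.  Positivity of inputs is guaranteed by panel validation.
    """
    q_cx = None
    if panel.serum_cxcl13 is not None:
        q_cx = panel.csf_cxcl13 / panel.serum_cxcl13
    q_alb = None
    if panel.csf_albumin is not None and panel.serum_albumin is not None:
        q_alb = panel.csf_albumin / panel.serum_albumin
    index = q_cx / q_alb if (q_cx is not None and q_alb is not None) else None
    return IndexResult(q_cxcl13=q_cx, q_albumin=q_alb, index=index)


def _classify_value(value: float, low_cut: float, high_cut: float) -> Group:
    # strictly above/below; a value exactly on a cut is indeterminate
    if value > high_cut:
        return Group.HIGH
    if value < low_cut:
        return Group.LOW
    return Group.INDETERMINATE


def classify(
    result: IndexResult,
    policy: ThresholdPolicy,
    csf_cxcl13: float,
) -> IndexResult:
    """Assign a group to a computed :class:`IndexResult`.

    The index rule wins whenever the index is computable; the CSF-only rule
    is the fallback for patients lacking serum CXCL13 or albumin data.
    """
    if result.index is not None:
        group = _classify_value(result.index, policy.index_low_cut, policy.index_high_cut)
        basis = Basis.INDEX
    else:
        group = _classify_value(csf_cxcl13, policy.csf_low_cut, policy.csf_high_cut)
        basis = Basis.CSF_ONLY
    return dataclasses.replace(result, group=group, basis=basis)


def stratify_cohort(
    records: Sequence[PatientRecord],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> dict[str, IndexResult]:
    """Classify every record; returns ``patient_id -> IndexResult``.

    Indeterminate patients are retained in the mapping (callers exclude them
    from contingency analyses downstream).
    """
    strata: dict[str, IndexResult] = {}
    for rec in records:
        try:
            result = classify(compute_index(rec.analytes), policy, rec.analytes.csf_cxcl13)
        except Exception as exc:  # pragma: no cover - panel validation makes this rare
            raise ValueError(f"patient {rec.patient_id!r}: {exc}") from exc
        strata[rec.patient_id] = result
    return strata


class IndexStratifier(ClassifierMixin, BaseEstimator):
    """Threshold-rule classifier assigning high/low/indeterminate groups.

    scikit-learn-compatible wrapper around the stratification rule so that it
    composes with pipelines and parameter search.  The thresholds are fixed
    clinical cuts, not learned: :meth:`fit` only validates parameters and
    records the label set.

    Parameters
    ----------
    index_high_cut, index_low_cut : float
        Cuts on the dimensionless CXCL13 index (defaults 30 and 20).
    csf_high_cut, csf_low_cut : float
        Cuts on CSF CXCL13 in pg/mL for the serum-free fallback
        (defaults 14 and 5).

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"csf_cxcl13": [10.0, 17.83], "serum_cxcl13": [100.0, None],
    ...                   "csf_albumin": [25.0, None], "serum_albumin": [4200.0, None]})
    >>> IndexStratifier().fit(X).predict(X).tolist()
    ['low', 'high']
    """

    def __init__(
        self,
        index_high_cut: float = 30.0,
        index_low_cut: float = 20.0,
        csf_high_cut: float = 14.0,
        csf_low_cut: float = 5.0,
    ):
        self.index_high_cut = index_high_cut
        self.index_low_cut = index_low_cut
        self.csf_high_cut = csf_high_cut
        self.csf_low_cut = csf_low_cut

    def _policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            index_high_cut=self.index_high_cut,
            index_low_cut=self.index_low_cut,
            csf_high_cut=self.csf_high_cut,
            csf_low_cut=self.csf_low_cut,
        )

    def fit(self, X=None, y=None) -> "IndexStratifier":
        """Validate thresholds; nothing is estimated from ``X``."""
        self._policy()  # raises on invalid cut ordering
        self.policy_ = self._policy()
        self.classes_ = np.array([g.value for g in (Group.HIGH, Group.INDETERMINATE, Group.LOW)])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Classify rows of an analyte table.

        ``X`` needs a ``csf_cxcl13`` column; ``serum_cxcl13``, ``csf_albumin``
        and ``serum_albumin`` are optional per row (missing = NaN) and drive
        the index-vs-CSF-only pathway choice.
        """
        if not hasattr(self, "policy_"):
            self.fit()
        frame = pd.DataFrame(X)
        if "csf_cxcl13" not in frame.columns:
            raise ValueError("X must have a 'csf_cxcl13' column")
        labels = []
        for _, row in frame.iterrows():
            panel = AnalytePanel(
                csf_cxcl13=row["csf_cxcl13"],
                serum_cxcl13=_opt(row.get("serum_cxcl13")),
                csf_albumin=_opt(row.get("csf_albumin")),
                serum_albumin=_opt(row.get("serum_albumin")),
            )
            res = classify(compute_index(panel), self.policy_, panel.csf_cxcl13)
            labels.append(res.group.value)
        return np.asarray(labels, dtype=object)


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def harmonization_agreement(
    records: Sequence[PatientRecord],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> Mapping[str, float]:
    """Agreement between the CSF-only rule and the index rule.

    For patients whose index is computable and whose CSF CXCL13 lies outside
    the CSF indeterminate zone, compares the group the CSF-only cuts would
    assign against the index-based group.  Returns counts and the
    disagreement rate — the empirical check behind the harmonized 5/14 pg/mL
    cuts.
    """
    n = agree = 0
    for rec in records:
        res = compute_index(rec.analytes)
        if res.index is None:
            continue
        csf = rec.analytes.csf_cxcl13
        csf_group = _classify_value(csf, policy.csf_low_cut, policy.csf_high_cut)
        if csf_group is Group.INDETERMINATE:
            continue
        idx_group = _classify_value(res.index, policy.index_low_cut, policy.index_high_cut)
        n += 1
        agree += idx_group is csf_group
    return {
        "n_compared": n,
        "n_agree": agree,
        "agreement_rate": agree / n if n else float("nan"),
        "disagreement_rate": 1 - agree / n if n else float("nan"),
    }
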