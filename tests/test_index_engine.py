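"""Index computation, threshold classification and cohort stratification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from cxcl13index import (
    AnalytePanel,
    Basis,
    Group,
    IndexResult,
    IndexStratifier,
    ThresholdPolicy,
    classify,
    compute_index,
    stratify_cohort,
)
from cxcl13index.index import harmonization_agreement

POLICY = ThresholdPolicy()

pos = st.floats(min_value=1e-3, max_value=1e5, allow_nan=False, allow_infinity=False)


def _panel(csf, serum=None, csf_alb=None, serum_alb=None):
    return AnalytePanel(
        csf_cxcl13=csf, serum_cxcl13=serum, csf_albumin=csf_alb, serum_albumin=serum_alb
    )


def test_compute_index_worked_example():
    """(10/100) / 0.005 = 20: quotients and index populated, no group set."""
    res = compute_index(_panel(10, serum=100, csf_alb=21, serum_alb=4200))
    assert res.q_cxcl13 == pytest.approx(0.1)
    assert res.q_albumin == pytest.approx(0.005)
    assert res.index == pytest.approx(20.0)
    assert res.group is None and res.basis is None


def test_compute_index_without_serum_leaves_index_absent():
    res = compute_index(_panel(10, csf_alb=21, serum_alb=4200))
    assert res.q_cxcl13 is None and res.index is None
    assert res.q_albumin == pytest.approx(0.005)


@given(a=pos, b=pos, c=pos, d=pos)
def test_index_equals_ratio_of_quotients(a, b, c, d):
    """Index always equals the independently recomputed (a/b)/(c/d)."""
    res = compute_index(_panel(a, serum=b, csf_alb=c, serum_alb=d))
    assert res.index == pytest.approx((a / b) / (c / d), rel=1e-9)


@given(a=pos, b=pos, c=pos, d=pos,
       k=st.floats(min_value=1e-3, max_value=1e3),
       m=st.floats(min_value=1e-3, max_value=1e3))
def test_index_invariant_under_common_rescaling(a, b, c, d, k, m):
    """Rescaling both albumin values by k and both CXCL13 values by m is a no-op."""
    base = compute_index(_panel(a, serum=b, csf_alb=c, serum_alb=d)).index
    scaled = compute_index(_panel(a * m, serum=b * m, csf_alb=c * k, serum_alb=d * k)).index
    assert scaled == pytest.approx(base, rel=1e-9)


@pytest.mark.parametrize(
    "index, expected",
    [
        (67.07, Group.HIGH),   # published high-group median
        (5.99, Group.LOW),     # published low-group median
        (25.0, Group.INDETERMINATE),
        (30.0, Group.INDETERMINATE),  # boundary ties are indeterminate
        (20.0, Group.INDETERMINATE),
        (math.nextafter(30.0, math.inf), Group.HIGH),
        (math.nextafter(20.0, 0.0), Group.LOW),
    ],
)
def test_classify_by_index(index, expected):
    res = classify(IndexResult(q_cxcl13=index * 0.005, q_albumin=0.005, index=index), POLICY, 10.0)
    assert res.group is expected
    assert res.basis is Basis.INDEX


def test_classify_through_panel_arithmetic():
    """End-to-end: serum chosen so the computed index is the published median."""
    serum = 17.83 / (67.07 * 0.005)
    res = classify(compute_index(_panel(17.83, serum, 21.0, 4200.0)), POLICY, 17.83)
    assert res.index == pytest.approx(67.07, rel=1e-9)
    assert res.group is Group.HIGH


@pytest.mark.parametrize(
    "csf, expected",
    [
        (17.83, Group.HIGH),  # published high-group CSF median
        (2.02, Group.LOW),    # published low-group CSF median
        (9.0, Group.INDETERMINATE),
        (14.0, Group.INDETERMINATE),
        (5.0, Group.INDETERMINATE),
    ],
)
def test_classify_csf_only_fallback(csf, expected):
    res = classify(compute_index(_panel(csf)), POLICY, csf)
    assert res.group is expected
    assert res.basis is Basis.CSF_ONLY


def test_index_rule_wins_when_both_computable():
    """High CSF value but low index: the index rule decides."""
    res = compute_index(_panel(20.0, serum=400.0, csf_alb=42, serum_alb=4200))
    assert res.index == pytest.approx(5.0)
    out = classify(res, POLICY, 20.0)
    assert out.group is Group.LOW and out.basis is Basis.INDEX


_RANK = {Group.LOW: 0, Group.INDETERMINATE: 1, Group.HIGH: 2}


@given(i1=st.floats(min_value=0.01, max_value=200), i2=st.floats(min_value=0.01, max_value=200))
def test_classification_monotone_in_index(i1, i2):
    """Raising the index never moves a patient from high toward low."""
    lo, hi = sorted((i1, i2))

    def group_of(ix):
        res = IndexResult(q_cxcl13=ix * 0.005, q_albumin=0.005, index=ix)
        return classify(res, POLICY, 10.0).group

    assert _RANK[group_of(lo)] <= _RANK[group_of(hi)]


def test_stratify_cohort_mixed(reference_records, reference_strata):
    assert set(reference_strata) == {r.patient_id for r in reference_records}
    groups = [reference_strata[r.patient_id].group for r in reference_records]
    assert groups.count(Group.HIGH) == 17
    assert groups.count(Group.LOW) == 20


def test_stratify_empty_cohort():
    assert stratify_cohort([]) == {}


def test_all_serum_missing_cohort_uses_csf_only(default_cohort):
    records = [
        r.model_copy(update={"analytes": r.analytes.model_copy(update={"serum_cxcl13": None})})
        for r in default_cohort.records
    ]
    strata = stratify_cohort(records)
    assert all(res.basis is Basis.CSF_ONLY for res in strata.values())


def test_harmonization_rules_agree_outside_the_gray_zone(xl_cohort):
    """For patients with CSF CXCL13 outside [5, 14] pg/mL, the CSF-only cuts
    assign the same group as the index for >=90% of simulated patients."""
    summary = harmonization_agreement(xl_cohort.records)
    assert summary["n_compared"] > 1000
    assert summary["agreement_rate"] >= 0.90


def test_threshold_policy_rejects_inverted_cuts():
    with pytest.raises(ValueError):
        ThresholdPolicy(index_high_cut=10, index_low_cut=20)


class TestIndexStratifier:
    X = pd.DataFrame(
        {
            "csf_cxcl13": [10.0, 17.83, 2.02, 9.0],
            "serum_cxcl13": [100.0, np.nan, np.nan, np.nan],
            "csf_albumin": [21.0, np.nan, np.nan, np.nan],
            "serum_albumin": [4200.0, np.nan, np.nan, np.nan],
        }
    )

    def test_predict_matches_rule(self):
        est = IndexStratifier().fit(self.X)
        assert est.predict(self.X).tolist() == ["indeterminate", "high", "low", "indeterminate"]

    def test_sklearn_params_round_trip(self):
        est = IndexStratifier(index_high_cut=40.0)
        cloned = clone(est)
        assert cloned.get_params()["index_high_cut"] == 40.0
        cloned.set_params(csf_low_cut=3.0)
        assert cloned.get_params()["csf_low_cut"] == 3.0

    def test_fit_validates_and_sets_classes(self):
        est = IndexStratifier().fit()
        assert sorted(est.classes_) == ["high", "indeterminate", "low"]
        with pytest.raises(ValueError):
            IndexStratifier(index_high_cut=5.0).fit()

    def test_agrees_with_stratify_cohort(self, reference_records, reference_strata):
        frame = pd.DataFrame(
            {
                "csf_cxcl13": [r.analytes.csf_cxcl13 for r in reference_records],
                "serum_cxcl13": [
                    np.nan if r.analytes.serum_cxcl13 is None else r.analytes.serum_cxcl13
                    for r in reference_records
                ],
                "csf_albumin": [r.analytes.csf_albumin for r in reference_records],
                "serum_albumin": [r.analytes.serum_albumin for r in reference_records],
            }
        )
        predicted = IndexStratifier().fit(frame).predict(frame)
        expected = [reference_strata[r.patient_id].group.value for r in reference_records]
        assert predicted.tolist() == expected
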