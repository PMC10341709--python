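"""Deterministic synthetic cohort matching the published group-level counts.

The motivating CIS/RIS study deposits no patient-level data, but its cohort
table fixes every group-level count: 17 index-high patients (14 CDMS
converters, 9 with clinical attacks, 16 OCB-positive, 7 with serum; new-
lesion MRI categories 4 none / 5 one / 8 more than one) and 20 index-low
patients (2 converters, 1 with attacks, 13 OCB-positive, 6 with serum;
14 lesion-free, 1 with one lesion MRI, 5 with no MRIs).  This module builds
a synthetic cohort realising exactly those counts, with biomarker values
pinned at the printed group medians, so that the stratification, the
confusion tables and the exact tests reproduce the published numbers when
run end to end.  Within-group joint assignments (which converter also had
attacks, etc.) are not published; attributes are assigned independently by
position, which leaves all group-level margins intact.
"""

from __future__ import annotations

from .cohort import AnalytePanel, Diagnosis, OutcomePanel, PatientRecord, Sex

# printed group medians, used as the pinned biomarker values
_HIGH_INDEX, _LOW_INDEX = 67.07, 5.99
_HIGH_CSF, _LOW_CSF = 17.83, 2.02
_Q_ALB = 0.005
_SERUM_ALBUMIN = 4200.0  # mg/dL


def _patient(
    pid: str,
    diagnosis: Diagnosis,
    age: float,
    sex: Sex,
    treatment: str,
    csf: float,
    index: float | None,
    converted: bool,
    ocb: bool,
    attacks: int,
    n_mris: int,
    lesion_mris: int,
    followup: float,
) -> PatientRecord:
    serum_cxcl13 = None if index is None else csf / (index * _Q_ALB)
    return PatientRecord(
        patient_id=pid,
        diagnosis=diagnosis,
        age=age,
        sex=sex,
        treatment=treatment,
        analytes=AnalytePanel(
            csf_cxcl13=csf,
            serum_cxcl13=serum_cxcl13,
            csf_albumin=_Q_ALB * _SERUM_ALBUMIN,
            serum_albumin=_SERUM_ALBUMIN,
            tnc=round(4.0 + 0.2 * csf),
        ),
        outcomes=OutcomePanel(
            converted_cdms=converted,
            ocb_positive=ocb,
            n_attacks=attacks,
            n_mris=n_mris,
            n_mris_with_new_lesions=lesion_mris,
            n_new_or_enhancing_lesions=lesion_mris,
            followup_years=followup,
        ),
    )


def reference_cohort() -> list[PatientRecord]:
    """The 37-patient synthetic cohort realising the published counts."""
    records: list[PatientRecord] = []

    # --- index-high group: 17 patients -------------------------------------
    high_treatments = (
        ["fingolimod"] * 2
        + ["glatiramer acetate + interferon"]
        + ["interferon"] * 5
        + ["natalizumab"] * 2
        + ["ocrelizumab"] * 2
        + ["none"] * 5
    )
    for i in range(17):
        # lesion-MRI categories: 4 none / 5 one / 8 more than one
        lesion_mris = 0 if i < 4 else (1 if i < 9 else 2)
        records.append(
            _patient(
                pid=f"H{i + 1:02d}",
                diagnosis=Diagnosis.CIS,
                age=35.51,
                sex=Sex.MALE if i < 3 else Sex.FEMALE,
                treatment=high_treatments[i],
                csf=_HIGH_CSF,
                index=_HIGH_INDEX if i < 7 else None,  # 7 with serum available
                converted=i < 14,
                ocb=i < 16,
                attacks=1 if i < 9 else 0,
                n_mris=4,
                lesion_mris=lesion_mris,
                followup=6.35,
            )
        )

    # --- index-low group: 20 patients ---------------------------------------
    low_treatments = (
        ["dimethyl fumarate"] * 2
        + ["glatiramer acetate"] * 3
        + ["interferon"] * 6
        + ["natalizumab"]
        + ["ozanimod"]
        + ["none"] * 7
    )
    for i in range(20):
        # 14 lesion-free with MRIs, 1 with one lesion MRI, 5 with no MRIs
        if i < 14:
            n_mris, lesion_mris = 3, 0
        elif i == 14:
            n_mris, lesion_mris = 3, 1
        else:
            n_mris, lesion_mris = 0, 0
        records.append(
            _patient(
                pid=f"L{i + 1:02d}",
                diagnosis=Diagnosis.RIS if i < 4 else Diagnosis.CIS,
                age=41.89,
                sex=Sex.MALE if i < 3 else Sex.FEMALE,
                treatment=low_treatments[i],
                csf=_LOW_CSF,
                index=_LOW_INDEX if i < 6 else None,  # 6 with serum available
                converted=i < 2,
                ocb=i < 13,
                attacks=1 if i < 1 else 0,
                n_mris=n_mris,
                lesion_mris=lesion_mris,
                followup=6.81,
            )
        )
    return records
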