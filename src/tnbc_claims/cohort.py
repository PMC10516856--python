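"""Cohort eligibility rules and analysis subcohorts.

A patient enters the TNBC cohort when, inside the study window, they have at
least one breast-cancer diagnosis claim (ICD-10 category C50, any subcode)
and at least one claim for an inclusion-list chemotherapy molecule; they are
18 or older at index; they have no hormone / targeted-therapy (exclusion
molecule) claim at any time; and they show no breast-cancer activity (C50
diagnosis or inclusion/exclusion drug claim) in the 2011 washout year.  The
index date is the date of the first C50 claim.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date

from .models import ClaimCategory, MoleculeCatalog, PatientRecord, normalize_icd10

DEFAULT_STUDY_WINDOW = (date(2012, 1, 1), date(2017, 12, 31))
WASHOUT_YEAR = 2011


class ExclusionReason(str, enum.Enum):
    NO_C50_IN_WINDOW = "no_c50_in_window"
    NO_INCLUSION_MOLECULE = "no_inclusion_molecule"
    UNDER_18 = "under_18"
    EXCLUSION_MOLECULE = "exclusion_molecule"
    ACTIVITY_IN_2011 = "activity_in_2011"


@dataclass(slots=True)
class EligibilityResult:
    patient_id: str
    eligible: bool
    exclusion_reasons: list[ExclusionReason] = field(default_factory=list)
    index_date: date | None = None
    age_missing: bool = False


def _is_c50(code: str) -> bool:
    return normalize_icd10(code)[:3] == "C50"


def evaluate_patient(
    patient: PatientRecord,
    catalog: MoleculeCatalog,
    window: tuple[date, date] = DEFAULT_STUDY_WINDOW,
) -> EligibilityResult:
    """Apply every eligibility rule and list all that fail.

    Rules are evaluated independently of claim order, so shuffling a
    patient's claims can never change the verdict.  Patients with missing
    age are retained and flagged (mirroring incomplete demographic capture
    in real claims data) rather than excluded.
    """
    lo, hi = window
    reasons: list[ExclusionReason] = []

    c50_in_window = sorted(
        c.service_date
        for c in patient.claims
        if c.category is ClaimCategory.DIAGNOSIS
        and _is_c50(c.code)
        and lo <= c.service_date <= hi
    )
    if not c50_in_window:
        reasons.append(ExclusionReason.NO_C50_IN_WINDOW)

    has_inclusion = any(
        c.category is ClaimCategory.DRUG and catalog.is_inclusion(c.code)
        for c in patient.claims
    )
    if not has_inclusion:
        reasons.append(ExclusionReason.NO_INCLUSION_MOLECULE)

    age = patient.age_at_first_claim
    if age is not None and age < 18:
        reasons.append(ExclusionReason.UNDER_18)

    if any(
        c.category is ClaimCategory.DRUG and catalog.is_exclusion(c.code)
        for c in patient.claims
    ):
        reasons.append(ExclusionReason.EXCLUSION_MOLECULE)

    # washout: any BC activity in 2011 = C50 diagnosis or any inclusion /
    # exclusion molecule claim dated in that calendar year
    if any(
        c.service_date.year == WASHOUT_YEAR
        and (
            (c.category is ClaimCategory.DIAGNOSIS and _is_c50(c.code))
            or (
                c.category is ClaimCategory.DRUG
                and (catalog.is_inclusion(c.code) or catalog.is_exclusion(c.code))
            )
        )
        for c in patient.claims
    ):
        reasons.append(ExclusionReason.ACTIVITY_IN_2011)

    eligible = not reasons
    return EligibilityResult(
        patient_id=patient.patient_id,
        eligible=eligible,
        exclusion_reasons=reasons,
        index_date=c50_in_window[0] if eligible else None,
        age_missing=age is None,
    )


def select_cohort(
    patients: list[PatientRecord],
    catalog: MoleculeCatalog | None = None,
    window: tuple[date, date] = DEFAULT_STUDY_WINDOW,
) -> list[EligibilityResult]:
    """Evaluate eligibility for every patient; empty input gives empty output."""
    catalog = catalog or MoleculeCatalog()
    return [evaluate_patient(p, catalog, window) for p in patients]


@dataclass(slots=True)
class SurgerySubcohort:
    """Early/locally-advanced patients with a breast-surgery claim (the HCRU
    analysis set), plus metastatic patients flagged by surgery status (used
    for the metastatic neoadjuvant-share computation)."""

    early_with_surgery: list[str]
    metastatic_with_surgery: list[str]
    metastatic_without_surgery: list[str]


def surgery_subcohort(
    patients: dict[str, PatientRecord],
    stage_labels: dict[str, str],
) -> SurgerySubcohort:
    """Split staged patients by the presence of a breast-surgery claim.

    ``stage_labels`` maps patient_id -> "early_locally_advanced" | "metastatic".
    """
    early_s: list[str] = []
    met_s: list[str] = []
    met_ns: list[str] = []
    for pid, stage in stage_labels.items():
        has_surgery = any(
            c.category is ClaimCategory.SURGERY for c in patients[pid].claims
        )
        if stage == "metastatic":
            (met_s if has_surgery else met_ns).append(pid)
        elif has_surgery:
            early_s.append(pid)
    return SurgerySubcohort(sorted(early_s), sorted(met_s), sorted(met_ns))
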