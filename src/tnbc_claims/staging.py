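"""Claims-based inference of disease stage at the index date.

Administrative claims carry no AJCC stage, so stage IV (metastatic) disease
is inferred from billing patterns: a patient is called metastatic when at
least two qualifying claims — metastatic ICD-10 diagnosis codes (C76–C80,
excluding C77.3) or codes from the configured metastatic-management set —
occur at least 15 days apart within a staging window running from 30 days
before to 183 days after the index date.  Everyone else is labelled
early / locally advanced (stages 0–III).  The two qualifying claims may mix
categories (one diagnosis code plus one management procedure counts), and
the same code on two qualifying dates suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

from .models import ClaimCategory, MoleculeCatalog, PatientRecord, is_metastatic_code

STAGE_EARLY = "early_locally_advanced"
STAGE_METASTATIC = "metastatic"

#: staging window endpoints relative to index, both inclusive:
#: "1 month before" = 30 days, "6 months after" = 183 days (6 x 30.4375 rounded)
WINDOW_BEFORE_DAYS = 30
WINDOW_AFTER_DAYS = 183
MIN_SEPARATION_DAYS = 15


@dataclass(slots=True)
class StageLabel:
    patient_id: str
    stage: str
    evidence: list[tuple[date, str]] = field(default_factory=list)


def qualifying_claims(
    patient: PatientRecord,
    index_date: date,
    catalog: MoleculeCatalog,
    window_before: int = WINDOW_BEFORE_DAYS,
    window_after: int = WINDOW_AFTER_DAYS,
) -> list[tuple[date, str]]:
    """All (date, code) pairs counting as metastatic evidence in the window."""
    lo = index_date - timedelta(days=window_before)
    hi = index_date + timedelta(days=window_after)
    out = []
    for c in patient.claims:
        if not (lo <= c.service_date <= hi):
            continue
        if c.category is ClaimCategory.DIAGNOSIS and is_metastatic_code(c.code, catalog):
            out.append((c.service_date, c.code))
        elif c.category is not ClaimCategory.DIAGNOSIS and catalog.is_metastatic_management(c.code):
            out.append((c.service_date, c.code))
    return out


def classify_stage(
    patient: PatientRecord,
    index_date: date | None,
    catalog: MoleculeCatalog | None = None,
    min_separation_days: int = MIN_SEPARATION_DAYS,
) -> StageLabel:
    """Label a patient metastatic or early/locally advanced at index.

    Metastatic requires some pair of qualifying claims separated by at least
    ``min_separation_days`` calendar days.  The evidence list reports every
    qualifying claim (it is non-empty but insufficient for, e.g., a lone
    metastatic code).  Raises ValueError when no index date is given —
    unstaged patients must be excluded upstream.
    """
    if index_date is None:
        raise ValueError(f"patient {patient.patient_id} has no index date; cannot stage")
    catalog = catalog or MoleculeCatalog()
    ev = qualifying_claims(patient, index_date, catalog)
    dates = sorted(d for d, _ in ev)
    metastatic = bool(dates) and (dates[-1] - dates[0]).days >= min_separation_days
    return StageLabel(
        patient_id=patient.patient_id,
        stage=STAGE_METASTATIC if metastatic else STAGE_EARLY,
        evidence=sorted(ev),
    )
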