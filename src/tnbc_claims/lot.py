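"""Line-of-therapy (LOT) construction from drug claims, and treatment-setting
classification.

The LOT algorithm groups a patient's chemotherapy claims into treatment
lines using two rules applied claim-by-claim in date order:

* **gap rule** — any drug claim at least 120 days after the previous drug
  claim opens a new line, whatever the molecule;
* **switch rule** — a claim for a molecule *not* in the current line's
  regimen, dated at least 60 days after the current line's start, opens a
  new line.

A molecule first seen inside the grouping window (28 days from line start)
forms part of the line's initial regimen; a new molecule appearing after the
window but before day 60 is treated as a regimen modification and extends
the molecule set rather than opening a line.  The gap rule is checked before
the switch rule when both could fire.

For early / locally-advanced patients with breast surgery, regimens are
split into neoadjuvant (starting strictly before the surgery date) and
adjuvant (on/after) blocks, and follow-on regimens are tagged *sequential*
(previous regimen ended at most 45 days earlier — a planned continuation,
e.g. AC followed by a taxane) or *progressive disease* (gap above 45 days).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from datetime import date

from .models import ClaimRecord, MoleculeCatalog, normalize_molecule

GROUPING_WINDOW_DAYS = 28
SWITCH_DAYS = 60
GAP_DAYS = 120
SEQUENTIAL_WINDOW_DAYS = 45


class LineTrigger(str, enum.Enum):
    INITIATION = "initiation"
    SWITCH_60D = "switch_60d"
    GAP_120D = "gap_120d"


class TreatmentSetting(str, enum.Enum):
    NAT_ONLY = "NAT_only"
    AT_ONLY = "AT_only"
    NAT_AT = "NAT_AT"
    NONE = "none"


class RegimenTag(str, enum.Enum):
    INITIAL = "initial"
    SEQUENTIAL = "sequential"
    PROGRESSIVE_DISEASE = "progressive_disease"


@dataclass(slots=True)
class Regimen:
    molecules: frozenset[str]
    label: str
    start_date: date
    end_date: date


@dataclass(slots=True)
class LineOfTherapy:
    line_index: int
    regimens: list[Regimen]
    start_date: date
    end_date: date
    start_trigger: LineTrigger
    claims: list[ClaimRecord] = field(default_factory=list)

    @property
    def molecules(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.regimens:
            out |= r.molecules
        return frozenset(out)

    @property
    def label(self) -> str:
        return self.regimens[0].label if self.regimens else ""


@dataclass(slots=True)
class SettingAssignment:
    patient_id: str
    setting: TreatmentSetting
    regimen_tags: list[RegimenTag]
    progression_flag: bool
    surgery_date: date | None


def build_lines(
    drug_claims: list[ClaimRecord],
    catalog: MoleculeCatalog | None = None,
    grouping_window: int = GROUPING_WINDOW_DAYS,
    switch_days: int = SWITCH_DAYS,
    gap_days: int = GAP_DAYS,
) -> list[LineOfTherapy]:
    """Group one patient's inclusion-molecule claims into lines of therapy.

    Claims must belong to a single patient; they are processed in service-date
    order (ties in input order).  Line 1 starts at the first claim; each
    line's end date is its last constituent claim.  Returns an empty list
    for an empty claim list.
    """
    catalog = catalog or MoleculeCatalog()
    claims = sorted(drug_claims, key=lambda c: c.service_date)
    if not claims:
        return []
    pids = {c.patient_id for c in claims}
    if len(pids) > 1:
        raise ValueError(f"claims from multiple patients: {sorted(pids)}")

    lines: list[LineOfTherapy] = []
    cur_claims: list[ClaimRecord] = []
    cur_molecules: set[str] = set()
    cur_start: date | None = None
    cur_trigger = LineTrigger.INITIATION
    last_claim_date: date | None = None

    def close_line() -> None:
        regimen = Regimen(
            molecules=frozenset(cur_molecules),
            label=catalog.regimen_label(cur_molecules),
            start_date=cur_start,
            end_date=cur_claims[-1].service_date,
        )
        lines.append(
            LineOfTherapy(
                line_index=len(lines) + 1,
                regimens=[regimen],
                start_date=cur_start,
                end_date=cur_claims[-1].service_date,
                start_trigger=cur_trigger,
                claims=list(cur_claims),
            )
        )

    for claim in claims:
        mol = normalize_molecule(claim.code)
        if cur_start is None:
            cur_start, cur_trigger = claim.service_date, LineTrigger.INITIATION
        else:
            new_trigger = None
            if (claim.service_date - last_claim_date).days >= gap_days:
                new_trigger = LineTrigger.GAP_120D
            elif (
                mol not in cur_molecules
                and (claim.service_date - cur_start).days >= switch_days
            ):
                new_trigger = LineTrigger.SWITCH_60D
            if new_trigger is not None:
                close_line()
                cur_claims, cur_molecules = [], set()
                cur_start, cur_trigger = claim.service_date, new_trigger
        cur_claims.append(claim)
        cur_molecules.add(mol)
        last_claim_date = claim.service_date
    close_line()
    return lines


def inclusion_drug_claims(
    claims: list[ClaimRecord], catalog: MoleculeCatalog
) -> list[ClaimRecord]:
    """The drug claims whose molecule is on the inclusion (TNBC chemo) list."""
    from .models import ClaimCategory

    return [
        c
        for c in claims
        if c.category is ClaimCategory.DRUG and catalog.is_inclusion(c.code)
    ]


def classify_setting(
    patient_id: str,
    lines: list[LineOfTherapy],
    surgery_date: date | None,
    sequential_window: int = SEQUENTIAL_WINDOW_DAYS,
) -> SettingAssignment:
    """Assign NAT / AT / NAT-AT setting for an early-stage surgery patient.

    Regimens starting strictly before the surgery date form the neoadjuvant
    block; those starting on or after it, the adjuvant block.  Raises
    ValueError without a surgery date (the setting analysis is defined only
    on the surgery subcohort).
    """
    if surgery_date is None:
        raise ValueError(f"patient {patient_id}: setting requires a surgery date")
    regimens = [r for ln in lines for r in ln.regimens]
    if not regimens:
        return SettingAssignment(patient_id, TreatmentSetting.NONE, [], False, surgery_date)
    nat = [r for r in regimens if r.start_date < surgery_date]
    at = [r for r in regimens if r.start_date >= surgery_date]
    if nat and at:
        setting = TreatmentSetting.NAT_AT
    elif nat:
        setting = TreatmentSetting.NAT_ONLY
    else:
        setting = TreatmentSetting.AT_ONLY
    tags, flag = tag_sequential_or_progression(regimens, sequential_window)
    return SettingAssignment(patient_id, setting, tags, flag, surgery_date)


def tag_sequential_or_progression(
    regimens: list[Regimen],
    sequential_window: int = SEQUENTIAL_WINDOW_DAYS,
) -> tuple[list[RegimenTag], bool]:
    """Tag each follow-on regimen as sequential or progressive disease.

    The gap is measured from the previous regimen's end date (its last claim)
    to the next regimen's start.  A gap within the 45-day window means a
    planned sequential regimen; a longer gap marks treatment for progressive
    disease and raises the patient-level progression flag.
    """
    tags: list[RegimenTag] = []
    flag = False
    for i, reg in enumerate(regimens):
        if i == 0:
            tags.append(RegimenTag.INITIAL)
            continue
        gap = (reg.start_date - regimens[i - 1].end_date).days
        if gap <= sequential_window:
            tags.append(RegimenTag.SEQUENTIAL)
        else:
            tags.append(RegimenTag.PROGRESSIVE_DISEASE)
            flag = True
    return tags, flag


def transition_matrix(
    lines_by_patient: dict[str, list[LineOfTherapy]]
) -> Counter[tuple[str, str]]:
    """Counts of adjacent regimen-label transitions across the cohort.

    Every adjacent pair of regimens for a patient contributes one count, so
    the total count equals Σ(regimens per patient − 1) — the edge list of a
    treatment-sequence Sankey diagram.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for lines in lines_by_patient.values():
        labels = [r.label for ln in lines for r in ln.regimens]
        for a, b in zip(labels, labels[1:]):
            counts[(a, b)] += 1
    return counts
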