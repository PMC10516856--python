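"""Domain types and code vocabularies for administrative-claims analysis.

The unit of data is a :class:`ClaimRecord` — one dated, costed service event
(diagnosis, drug, procedure, visit, ER visit, admission, surgery or
radiotherapy) for one patient.  A :class:`PatientRecord` bundles a patient's
demographics with their date-sorted claims.  The :class:`MoleculeCatalog`
holds the code vocabularies the analysis is parameterised by: which molecules
define breast-cancer chemotherapy (inclusion), which molecules disqualify a
patient as non-TNBC (hormone / HER2-targeted therapy, exclusion), which
procedure codes indicate metastatic-disease management, and how molecule
combinations map to regimen labels such as "AC".
"""

from __future__ import annotations

import enum
import unicodedata
from dataclasses import dataclass, field
from datetime import date


class ClaimCategory(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    DRUG = "drug"
    PROCEDURE = "procedure"
    OUTPATIENT_VISIT = "outpatient_visit"
    ER_VISIT = "er_visit"
    INPATIENT_ADMISSION = "inpatient_admission"
    SURGERY = "surgery"
    RADIOTHERAPY = "radiotherapy"


class CareSetting(str, enum.Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class Region(str, enum.Enum):
    NORTH = "North"
    NORTHEAST = "Northeast"
    CENTRAL_WEST = "Central-West"
    SOUTHEAST = "Southeast"
    SOUTH = "South"
    UNKNOWN = "unknown"


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code to the dotted dialect, e.g. ``C773`` -> ``C77.3``.

    Brazilian claims exports use both dotted and undotted forms; all internal
    comparisons are done on the dotted form.  Whitespace is stripped and the
    code upper-cased.  Codes too short to carry a subcode are returned as-is.
    """
    c = code.strip().upper().replace(".", "")
    if len(c) > 3:
        return c[:3] + "." + c[3:]
    return c


def normalize_molecule(name: str) -> str:
    """Lowercase-ASCII molecule name for catalog lookup (strips accents)."""
    folded = unicodedata.normalize("NFKD", name.strip().lower())
    return "".join(ch for ch in folded if not unicodedata.combining(ch))


@dataclass(slots=True)
class ClaimRecord:
    """One dated, costed service event for a patient.

    ``code`` carries the ICD-10 code for diagnoses, the molecule name for
    drugs, and a procedure code otherwise; it may be empty for visits.
    ``cost_brl_nominal`` is in nominal (service-date) Brazilian reais.
    ``admission_days`` is only nonzero for inpatient admissions.
    """

    patient_id: str
    service_date: date
    category: ClaimCategory
    code: str = ""
    setting: CareSetting = CareSetting.OUTPATIENT
    cost_brl_nominal: float = 0.0
    admission_days: int = 0

    def __post_init__(self) -> None:
        self.category = ClaimCategory(self.category)
        self.setting = CareSetting(self.setting)
        if self.cost_brl_nominal < 0:
            raise ValueError(
                f"negative cost {self.cost_brl_nominal} for patient {self.patient_id}"
            )
        if self.admission_days < 0:
            raise ValueError("admission_days must be >= 0")
        if self.admission_days and self.category is not ClaimCategory.INPATIENT_ADMISSION:
            raise ValueError("admission_days only allowed on inpatient_admission claims")
        if self.category is ClaimCategory.DRUG and not self.code.strip():
            raise ValueError("drug claims require a molecule name in `code`")


@dataclass(slots=True)
class PatientRecord:
    """A patient's demographics plus their claims, sorted by service date."""

    patient_id: str
    age_at_first_claim: int | None = None
    region: Region = Region.UNKNOWN
    claims: list[ClaimRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        for c in self.claims:
            if c.patient_id != self.patient_id:
                raise ValueError(
                    f"claim patient_id {c.patient_id!r} != {self.patient_id!r}"
                )
        self.claims.sort(key=lambda c: c.service_date)

    def claims_of(self, *categories: ClaimCategory) -> list[ClaimRecord]:
        wanted = set(categories)
        return [c for c in self.claims if c.category in wanted]


#: Molecules named as TNBC chemotherapy in the study results.  The source
#: study's full supplementary inclusion list is not public; this default is
#: the documented approximation and is overridable via catalog config.
DEFAULT_INCLUSION_MOLECULES = frozenset(
    {
        "doxorubicin",
        "cyclophosphamide",
        "paclitaxel",
        "docetaxel",
        "carboplatin",
        "cisplatin",
        "gemcitabine",
        "capecitabine",
        "fluorouracil",
        "bevacizumab",
    }
)

#: Hormone and HER2-targeted therapies: their presence anywhere in a
#: patient's history marks the tumour as non-triple-negative.
DEFAULT_EXCLUSION_MOLECULES = frozenset(
    {
        "tamoxifen",
        "anastrozole",
        "letrozole",
        "exemestane",
        "fulvestrant",
        "trastuzumab",
        "pertuzumab",
        "lapatinib",
    }
)

DEFAULT_METASTATIC_ICD_PREFIXES = frozenset({"C76", "C77", "C78", "C79", "C80"})

#: C77.3 (axillary / upper-limb lymph-node secondaries) is regional rather
#: than distant spread and is excluded from the metastatic evidence set.
METASTATIC_EXCLUDED_SUBCODES = frozenset({"C77.3"})

DEFAULT_REGIMEN_NAMES: dict[frozenset[str], str] = {
    frozenset({"doxorubicin", "cyclophosphamide"}): "AC",
    frozenset({"doxorubicin", "cyclophosphamide", "paclitaxel"}): "AC-T",
    frozenset({"doxorubicin", "cyclophosphamide", "docetaxel"}): "AC-T",
    frozenset(
        {"fluorouracil", "doxorubicin", "cyclophosphamide", "docetaxel"}
    ): "FAC-T",
    frozenset({"docetaxel", "cyclophosphamide"}): "TC",
}


@dataclass
class MoleculeCatalog:
    """Code vocabularies: inclusion / exclusion molecules, metastatic codes,
    and regimen naming.

    All molecule names are normalized (lowercase ASCII) on construction and
    on lookup, so case or accent variants in claims exports cannot cause
    silent misses.
    """

    inclusion_molecules: frozenset[str] = DEFAULT_INCLUSION_MOLECULES
    exclusion_molecules: frozenset[str] = DEFAULT_EXCLUSION_MOLECULES
    metastatic_management_codes: frozenset[str] = frozenset()
    metastatic_icd_prefixes: frozenset[str] = DEFAULT_METASTATIC_ICD_PREFIXES
    regimen_names: dict[frozenset[str], str] = field(
        default_factory=lambda: dict(DEFAULT_REGIMEN_NAMES)
    )

    def __post_init__(self) -> None:
        self.inclusion_molecules = frozenset(
            normalize_molecule(m) for m in self.inclusion_molecules
        )
        self.exclusion_molecules = frozenset(
            normalize_molecule(m) for m in self.exclusion_molecules
        )
        overlap = self.inclusion_molecules & self.exclusion_molecules
        if overlap:
            raise ValueError(f"molecules in both inclusion and exclusion sets: {sorted(overlap)}")
        self.metastatic_management_codes = frozenset(
            c.strip().upper() for c in self.metastatic_management_codes
        )
        self.metastatic_icd_prefixes = frozenset(
            normalize_icd10(p) for p in self.metastatic_icd_prefixes
        )
        self.regimen_names = {
            frozenset(normalize_molecule(m) for m in mols): label
            for mols, label in self.regimen_names.items()
        }

    def is_inclusion(self, molecule: str) -> bool:
        return normalize_molecule(molecule) in self.inclusion_molecules

    def is_exclusion(self, molecule: str) -> bool:
        return normalize_molecule(molecule) in self.exclusion_molecules

    def is_metastatic_management(self, code: str) -> bool:
        return code.strip().upper() in self.metastatic_management_codes

    def regimen_label(self, molecules: frozenset[str] | set[str]) -> str:
        """Catalog name for a molecule combination, else sorted names joined."""
        key = frozenset(normalize_molecule(m) for m in molecules)
        return self.regimen_names.get(key, "+".join(sorted(key)))


def is_metastatic_code(code: str, catalog: MoleculeCatalog | None = None) -> bool:
    """True iff an ICD-10 code counts as evidence of distant metastasis.

    A code qualifies when its three-character category prefix is one of the
    catalog's metastatic prefixes (C76–C80 by default) and it is not the
    excluded subcode C77.3, in either dotted or undotted dialect.  Malformed
    codes simply return False.
    """
    if catalog is None:
        catalog = MoleculeCatalog()
    norm = normalize_icd10(code)
    if norm in METASTATIC_EXCLUDED_SUBCODES:
        return False
    return norm[:3] in catalog.metastatic_icd_prefixes
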