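"""Readers and writers for the tabular claims interchange format.

Claims travel as CSV with a fixed header (one row per claim), demographics
as a companion CSV keyed by patient id, and the molecule catalog as a
YAML/JSON config.  Dates are ISO-8601 (YYYY-MM-DD).  Reading validates row
by row and reports every offending row number rather than stopping at the
first.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .models import (
    CareSetting,
    ClaimCategory,
    ClaimRecord,
    MoleculeCatalog,
    PatientRecord,
    Region,
)

CLAIMS_COLUMNS = [
    "patient_id",
    "service_date",
    "category",
    "code",
    "setting",
    "cost_brl_nominal",
    "admission_days",
]

DEMOGRAPHICS_COLUMNS = ["patient_id", "age_at_first_claim", "region"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowValidationError(ValueError):
    """One or more rows failed validation; carries (row number, message) pairs."""

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:20])
        extra = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{extra}")


def _parse_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    return date.fromisoformat(str(value).strip())


def read_claims(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    demographics: str | Path | None = None,
) -> list[PatientRecord]:
    """Read a claims CSV (plus optional demographics CSV) into PatientRecords.

    Parameters
    ----------
    path:
        Claims CSV.  Must contain the standard columns, possibly under
        different names supplied via ``schema``.
    schema:
        Optional mapping from standard column name to the column name used
        in the file, e.g. ``{"patient_id": "member_id"}``.
    demographics:
        Optional demographics CSV (patient_id, age_at_first_claim, region).

    Returns patients with claims grouped per patient and sorted by service
    date.  Raises :class:`SchemaError` for missing columns and
    :class:`RowValidationError` listing every unparseable row (1-based data
    row numbers, header excluded).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"claims file {path} missing required column(s): {missing}")

    demo: dict[str, tuple[int | None, Region]] = {}
    if demographics is not None:
        demo = read_demographics(demographics)

    claims_by_patient: dict[str, list[ClaimRecord]] = {}
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = ClaimRecord(
                patient_id=str(row.patient_id),
                service_date=_parse_date(row.service_date),
                category=ClaimCategory(str(row.category)),
                code=str(row.code),
                setting=CareSetting(str(row.setting)),
                cost_brl_nominal=float(row.cost_brl_nominal),
                admission_days=int(row.admission_days or 0),
            )
        except (ValueError, KeyError) as exc:
            errors.append((i, str(exc)))
            continue
        claims_by_patient.setdefault(rec.patient_id, []).append(rec)
    if errors:
        raise RowValidationError(errors)

    patients = []
    for pid in claims_by_patient:
        age, region = demo.get(pid, (None, Region.UNKNOWN))
        patients.append(
            PatientRecord(
                patient_id=pid,
                age_at_first_claim=age,
                region=region,
                claims=claims_by_patient[pid],
            )
        )
    # patients with demographics but no claims still exist in the cohort
    for pid, (age, region) in demo.items():
        if pid not in claims_by_patient:
            patients.append(
                PatientRecord(patient_id=pid, age_at_first_claim=age, region=region)
            )
    patients.sort(key=lambda p: p.patient_id)
    return patients


def read_demographics(path: str | Path) -> dict[str, tuple[int | None, Region]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"demographics file {path} missing column(s): {missing}")
    out: dict[str, tuple[int | None, Region]] = {}
    for row in df.itertuples(index=False):
        age = int(row.age_at_first_claim) if str(row.age_at_first_claim).strip() else None
        region = Region(row.region) if str(row.region).strip() else Region.UNKNOWN
        out[str(row.patient_id)] = (age, region)
    return out


def claims_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        (
            c.patient_id,
            c.service_date.isoformat(),
            c.category.value,
            c.code,
            c.setting.value,
            f"{c.cost_brl_nominal:.2f}",
            c.admission_days,
        )
        for p in patients
        for c in p.claims
    ]
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def write_claims(
    patients: Sequence[PatientRecord],
    path: str | Path,
    demographics_path: str | Path | None = None,
) -> Path:
    """Write patients to a claims CSV (costs stored to 2 decimals).

    Round-trips with :func:`read_claims`.  If ``demographics_path`` is given
    the demographics table is written alongside.
    """
    path = Path(path)
    claims_to_frame(patients).to_csv(path, index=False)
    if demographics_path is not None:
        write_demographics(patients, demographics_path)
    return path


def write_demographics(patients: Sequence[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (
            p.patient_id,
            "" if p.age_at_first_claim is None else p.age_at_first_claim,
            p.region.value,
        )
        for p in patients
    ]
    pd.DataFrame(rows, columns=DEMOGRAPHICS_COLUMNS).to_csv(path, index=False)
    return path


def load_catalog(path: str | Path) -> MoleculeCatalog:
    """Load a MoleculeCatalog from a YAML or JSON config file.

    Recognised keys: inclusion_molecules, exclusion_molecules,
    metastatic_management_codes, metastatic_icd_prefixes, regimen_names
    (mapping regimen label -> list of molecules).  Absent keys fall back to
    the documented defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    kwargs = {}
    for key in ("inclusion_molecules", "exclusion_molecules", "metastatic_management_codes", "metastatic_icd_prefixes"):
        if key in data:
            kwargs[key] = frozenset(data[key])
    if "regimen_names" in data:
        kwargs["regimen_names"] = {
            frozenset(mols): label for label, mols in data["regimen_names"].items()
        }
    return MoleculeCatalog(**kwargs)


def dump_catalog(catalog: MoleculeCatalog, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "inclusion_molecules": sorted(catalog.inclusion_molecules),
        "exclusion_molecules": sorted(catalog.exclusion_molecules),
        "metastatic_management_codes": sorted(catalog.metastatic_management_codes),
        "metastatic_icd_prefixes": sorted(catalog.metastatic_icd_prefixes),
        "regimen_names": {
            label: sorted(mols) for mols, label in catalog.regimen_names.items()
        },
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
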