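"""Cohort-flow accounting, share computations, publication-shaped tables,
and the end-to-end pipeline.

Percentages are stored as (numerator, denominator) pairs and rendered only
at report time, so every printed share can be recomputed exactly from its
stored counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import metrics as M
from .cohort import (
    DEFAULT_STUDY_WINDOW,
    EligibilityResult,
    SurgerySubcohort,
    select_cohort,
    surgery_subcohort,
)
from .lot import (
    LineOfTherapy,
    SettingAssignment,
    TreatmentSetting,
    build_lines,
    classify_setting,
    inclusion_drug_claims,
    transition_matrix,
)
from .models import ClaimCategory, MoleculeCatalog, PatientRecord
from .staging import STAGE_EARLY, STAGE_METASTATIC, StageLabel, classify_stage


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (the convention of printed clinical tables;
    banker's rounding would print 0.5 cases differently)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def share(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage numerator/denominator, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, decimals)


def relative_excess(a: float, b: float, decimals: int = 0) -> float:
    """Percentage by which `a` exceeds `b`: 100 x (a - b) / b, half-up."""
    if b <= 0:
        raise ValueError("baseline must be positive")
    return round_half_up(100.0 * (a - b) / b, decimals)


@dataclass(slots=True)
class FlowStep:
    name: str
    numerator: int
    denominator: int

    @property
    def pct(self) -> float:
        return share(self.numerator, self.denominator, 1)


@dataclass
class CohortFlowReport:
    """Counts (with denominators) at each selection / classification step."""

    steps: list[FlowStep] = field(default_factory=list)

    def add(self, name: str, numerator: int, denominator: int) -> None:
        if numerator > denominator:
            raise ValueError(f"flow step {name}: child count exceeds parent")
        self.steps.append(FlowStep(name, numerator, denominator))

    def as_dict(self) -> dict:
        return {
            s.name: {"n": s.numerator, "denominator": s.denominator, "pct": s.pct}
            for s in self.steps
        }


def regimen_frequency_table(
    lines_by_patient: dict[str, list[LineOfTherapy]],
    strata: dict[str, str],
) -> pd.DataFrame:
    """Patients by first-regimen label within each stratum, with shares.

    ``strata`` maps patient_id -> stratum name (setting or LOT label).
    Shares are percentages of the stratum and sum to 100 up to rounding.
    Patients without lines are skipped; empty strata produce no rows.
    """
    rows = []
    by_stratum: dict[str, list[str]] = {}
    for pid, lines in lines_by_patient.items():
        if not lines or pid not in strata:
            continue
        by_stratum.setdefault(strata[pid], []).append(lines[0].label)
    for stratum in sorted(by_stratum):
        labels = by_stratum[stratum]
        counts = pd.Series(labels).value_counts()
        for label, n in counts.items():
            rows.append(
                {
                    "stratum": stratum,
                    "regimen": label,
                    "n": int(n),
                    "pct": share(int(n), len(labels), 1),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "regimen", "n", "pct"])


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, keyed for report rendering."""

    eligibility: list[EligibilityResult]
    stages: dict[str, StageLabel]
    subcohort: SurgerySubcohort
    lines_by_patient: dict[str, list[LineOfTherapy]]
    settings: dict[str, SettingAssignment]
    flow: CohortFlowReport
    hcru_by_stage: dict[str, dict[str, M.PPPMEstimate]]
    costs_by_stage: dict[str, dict[str, M.PPPMEstimate]]
    duration_tables: dict[str, M.DurationSummary]
    transitions: dict[tuple[str, str], int]
    regimen_table: pd.DataFrame


EVENT_CATEGORIES = {
    "inpatient_admission": ClaimCategory.INPATIENT_ADMISSION,
    "er_visit": ClaimCategory.ER_VISIT,
    "outpatient_visit": ClaimCategory.OUTPATIENT_VISIT,
    "procedure": ClaimCategory.PROCEDURE,
}


def run_pipeline(
    patients: list[PatientRecord],
    catalog: MoleculeCatalog | None = None,
    window: tuple[date, date] = DEFAULT_STUDY_WINDOW,
    currency: M.CurrencyParameters | None = None,
) -> PipelineResult:
    """Select -> stage -> build lines -> classify settings -> metrics.

    The HCRU/cost analysis set follows the study design: early / locally
    advanced patients enter only with a breast-surgery claim; metastatic
    patients all enter.
    """
    catalog = catalog or MoleculeCatalog()
    currency = currency or M.CurrencyParameters()
    by_id = {p.patient_id: p for p in patients}

    eligibility = select_cohort(patients, catalog, window)
    eligible = [e for e in eligibility if e.eligible]

    stages: dict[str, StageLabel] = {}
    for e in eligible:
        stages[e.patient_id] = classify_stage(by_id[e.patient_id], e.index_date, catalog)
    stage_names = {pid: s.stage for pid, s in stages.items()}

    sub = surgery_subcohort(by_id, stage_names)

    lines_by_patient: dict[str, list[LineOfTherapy]] = {}
    for e in eligible:
        drug_claims = inclusion_drug_claims(by_id[e.patient_id].claims, catalog)
        lines_by_patient[e.patient_id] = build_lines(drug_claims, catalog)

    settings: dict[str, SettingAssignment] = {}
    for pid in sub.early_with_surgery:
        surgery_dates = [
            c.service_date
            for c in by_id[pid].claims
            if c.category is ClaimCategory.SURGERY
        ]
        settings[pid] = classify_setting(
            pid, lines_by_patient[pid], min(surgery_dates)
        )

    # ---- cohort flow -----------------------------------------------------
    flow = CohortFlowReport()
    n_total = len(patients)
    n_eligible = len(eligible)
    n_early = sum(1 for s in stage_names.values() if s == STAGE_EARLY)
    n_met = n_eligible - n_early
    flow.add("eligible_tnbc", n_eligible, max(n_total, 1))
    if n_eligible:
        flow.add("early_locally_advanced", n_early, n_eligible)
        flow.add("metastatic", n_met, n_eligible)
    if n_early:
        flow.add("early_surgery_subcohort", len(sub.early_with_surgery), n_early)
    if n_met:
        flow.add("metastatic_with_surgery", len(sub.metastatic_with_surgery), n_met)
    for name in (
        TreatmentSetting.AT_ONLY,
        TreatmentSetting.NAT_ONLY,
        TreatmentSetting.NAT_AT,
    ):
        n = sum(1 for s in settings.values() if s.setting is name)
        if sub.early_with_surgery:
            flow.add(f"setting_{name.value}", n, len(sub.early_with_surgery))

    # ---- analysis sets for HCRU / costs ---------------------------------
    analysis_sets = {
        STAGE_EARLY: list(sub.early_with_surgery),
        STAGE_METASTATIC: sorted(
            pid for pid, s in stage_names.items() if s == STAGE_METASTATIC
        ),
    }

    hcru: dict[str, dict[str, M.PPPMEstimate]] = {}
    costs: dict[str, dict[str, M.PPPMEstimate]] = {}
    for stage, pids in analysis_sets.items():
        counts = {name: 0 for name in EVENT_CATEGORIES}
        exposure_total = 0.0
        pppm_total, pppm_inpat, pppm_outpat = [], [], []
        for pid in pids:
            lines = lines_by_patient.get(pid, [])
            if not lines:
                continue
            kept, exposure = M.restrict_to_treatment_periods(by_id[pid].claims, lines)
            exposure_total += exposure
            for name, cat in EVENT_CATEGORIES.items():
                counts[name] += sum(1 for c in kept if c.category is cat)
            breakdown = M.aggregate_costs(kept, currency)
            pppm_total.append(breakdown.total_brl / exposure)
            pppm_inpat.append(breakdown.inpatient_brl / exposure)
            pppm_outpat.append(breakdown.outpatient_brl / exposure)
        if exposure_total <= 0:
            continue
        hcru[stage] = {
            name: M.pppm_count(counts[name], exposure_total, len(pids))
            for name in EVENT_CATEGORIES
        }
        costs[stage] = {
            "total_brl": M.pppm_cost(pppm_total, exposure_total),
            "inpatient_brl": M.pppm_cost(pppm_inpat, exposure_total),
            "outpatient_brl": M.pppm_cost(pppm_outpat, exposure_total),
        }

    # ---- duration / TTNT tables -----------------------------------------
    durations: dict[str, M.DurationSummary] = {}
    lot1_dur, ttnt_12 = [], []
    met_pids = analysis_sets[STAGE_METASTATIC]
    for pid in met_pids:
        lines = lines_by_patient.get(pid, [])
        if lines:
            lot1_dur.append(M.treatment_duration(lines[0]))
        if len(lines) >= 2:
            ttnt_12.append(M.ttnt(lines[0], lines[1]))
    if lot1_dur:
        durations["met_lot1_duration_months"] = M.summarize(lot1_dur)
    if ttnt_12:
        durations["met_ttnt_lot1_lot2_months"] = M.summarize(ttnt_12)

    # ---- treatment-pattern outputs --------------------------------------
    strata = {pid: s.setting.value for pid, s in settings.items()}
    for pid in met_pids:
        strata[pid] = "mTNBC_LOT1"
    regimen_table = regimen_frequency_table(lines_by_patient, strata)
    transitions = dict(transition_matrix(lines_by_patient))

    return PipelineResult(
        eligibility=eligibility,
        stages=stages,
        subcohort=sub,
        lines_by_patient=lines_by_patient,
        settings=settings,
        flow=flow,
        hcru_by_stage=hcru,
        costs_by_stage=costs,
        duration_tables=durations,
        transitions=transitions,
        regimen_table=regimen_table,
    )


# --------------------------------------------------------------------------
# CSV / JSON rendering of the report bundle
# --------------------------------------------------------------------------

def write_report_bundle(result: PipelineResult, outdir: str | Path,
                        currency: M.CurrencyParameters | None = None) -> dict[str, Path]:
    """Write all pipeline outputs as CSV/JSON under ``outdir``."""
    currency = currency or M.CurrencyParameters()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    elig = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "eligible": e.eligible,
                "exclusion_reasons": ";".join(r.value for r in e.exclusion_reasons),
                "index_date": e.index_date.isoformat() if e.index_date else "",
            }
            for e in result.eligibility
        ]
    )
    paths["eligibility"] = outdir / "eligibility.csv"
    elig.to_csv(paths["eligibility"], index=False)

    stage = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "stage": s.stage,
                "n_evidence_claims": len(s.evidence),
            }
            for s in result.stages.values()
        ]
    )
    paths["stage"] = outdir / "stage.csv"
    stage.to_csv(paths["stage"], index=False)

    line_rows = []
    for pid, lines in result.lines_by_patient.items():
        setting = result.settings.get(pid)
        for ln in lines:
            tag = ""
            if setting and ln.line_index - 1 < len(setting.regimen_tags):
                tag = setting.regimen_tags[ln.line_index - 1].value
            line_rows.append(
                {
                    "patient_id": pid,
                    "line_index": ln.line_index,
                    "regimen_label": ln.label,
                    "start": ln.start_date.isoformat(),
                    "end": ln.end_date.isoformat(),
                    "trigger": ln.start_trigger.value,
                    "setting_tag": tag,
                }
            )
    paths["lines"] = outdir / "lines.csv"
    pd.DataFrame(
        line_rows,
        columns=[
            "patient_id", "line_index", "regimen_label", "start", "end",
            "trigger", "setting_tag",
        ],
    ).to_csv(paths["lines"], index=False)

    trans = pd.DataFrame(
        [
            {"from": a, "to": b, "count": n}
            for (a, b), n in sorted(result.transitions.items())
        ],
        columns=["from", "to", "count"],
    )
    paths["transitions"] = outdir / "transitions.csv"
    trans.to_csv(paths["transitions"], index=False)

    dur = pd.DataFrame(
        [
            {
                "measure": name, "n": s.n,
                "mean": round_half_up(s.mean, 2), "sd": round_half_up(s.sd, 2),
                "median": round_half_up(s.median, 2),
                "iqi_low": round_half_up(s.iqi_low, 2),
                "iqi_high": round_half_up(s.iqi_high, 2),
            }
            for name, s in result.duration_tables.items()
        ],
        columns=["measure", "n", "mean", "sd", "median", "iqi_low", "iqi_high"],
    )
    paths["durations"] = outdir / "durations.csv"
    dur.to_csv(paths["durations"], index=False)

    hcru_rows = [
        {
            "stage": stage_name, "event": name,
            "pppm": round_half_up(est.point, 2),
            "ci_low": round_half_up(est.ci_low, 2),
            "ci_high": round_half_up(est.ci_high, 2),
            "n_patients": est.n_patients,
            "exposure_months": round_half_up(est.total_exposure_months, 1),
        }
        for stage_name, ests in result.hcru_by_stage.items()
        for name, est in ests.items()
    ]
    paths["hcru"] = outdir / "hcru.csv"
    pd.DataFrame(
        hcru_rows,
        columns=["stage", "event", "pppm", "ci_low", "ci_high", "n_patients",
                 "exposure_months"],
    ).to_csv(paths["hcru"], index=False)

    cost_rows = []
    for stage_name, ests in result.costs_by_stage.items():
        for name, est in ests.items():
            usd = est.point * currency.brl_to_usd
            cost_rows.append(
                {
                    "stage": stage_name,
                    "component": name.replace("_brl", ""),
                    "pppm_brl": round_half_up(est.point, 2),
                    "ci_low_brl": round_half_up(est.ci_low, 2),
                    "ci_high_brl": round_half_up(est.ci_high, 2),
                    "pppm_usd": round_half_up(usd, 2),
                    "n_patients": est.n_patients,
                }
            )
    paths["costs"] = outdir / "costs.csv"
    pd.DataFrame(
        cost_rows,
        columns=["stage", "component", "pppm_brl", "ci_low_brl", "ci_high_brl",
                 "pppm_usd", "n_patients"],
    ).to_csv(paths["costs"], index=False)

    paths["regimens"] = outdir / "regimen_frequency.csv"
    result.regimen_table.to_csv(paths["regimens"], index=False)

    paths["flow"] = outdir / "flow_report.json"
    paths["flow"].write_text(json.dumps(result.flow.as_dict(), indent=2) + "\n")
    return paths
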