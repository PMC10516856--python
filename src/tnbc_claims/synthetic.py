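"""Synthetic administrative-claims generator with exported ground truth.

Real oncology claims databases are proprietary, so every downstream stage of
the pipeline is exercised against simulated claims that reproduce the
statistical structure the analysis assumes:

* dated ICD-10 C50 diagnosis claims defining the index date, and paired
  metastatic-code claims (C76–C80) planting stage evidence;
* cyclic chemotherapy drug claims drawn from per-stage / per-line regimen
  menus (AC, taxanes, bevacizumab + paclitaxel, gemcitabine, capecitabine,
  ...), laid out so the line-of-therapy rules recover the planned lines
  exactly;
* breast-surgery claims splitting early-stage treatment into neoadjuvant
  and adjuvant blocks;
* ER-visit / outpatient-visit / procedure / admission events drawn from a
  Poisson process at configured per-patient-per-month rates over treatment
  periods only, with gamma-distributed nominal-BRL costs;
* contaminant patients (screening-only C50, hormone-therapy users, pre-2012
  activity), each violating exactly the eligibility rule its kind names.

Randomness: one global seed spawns a named substream per patient
(``SeedSequence(seed, patient_index)``), so adding or removing patients
never perturbs the draws of others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .models import (
    CareSetting,
    ClaimCategory,
    ClaimRecord,
    PatientRecord,
    Region,
)

Menu = list[tuple[list[str], float]]

DEFAULT_REGIMEN_MENUS: dict[str, Menu] = {
    # adjuvant menu for early-stage disease: anthracycline and taxane based
    "early_at": [
        (["doxorubicin", "cyclophosphamide"], 0.45),
        (["docetaxel", "cyclophosphamide"], 0.20),
        (["docetaxel"], 0.15),
        (["paclitaxel"], 0.20),
    ],
    # neoadjuvant menu: mostly AC (AC-T arises as AC + sequential taxane)
    "early_nat": [
        (["doxorubicin", "cyclophosphamide"], 0.70),
        (["doxorubicin"], 0.30),
    ],
    # planned sequential follow-on after an anthracycline block
    "early_seq": [
        (["paclitaxel"], 0.60),
        (["docetaxel"], 0.40),
    ],
    "met_nat": [
        (["doxorubicin", "cyclophosphamide"], 0.50),
        (["doxorubicin"], 0.244),
        (["paclitaxel"], 0.256),
    ],
    "met_lot1": [
        (["bevacizumab", "paclitaxel"], 0.216),
        (["doxorubicin", "cyclophosphamide"], 0.25),
        (["paclitaxel"], 0.18),
        (["docetaxel"], 0.12),
        (["carboplatin", "gemcitabine"], 0.10),
        (["capecitabine"], 0.134),
    ],
    "met_lot2": [
        (["paclitaxel"], 0.25),
        (["docetaxel"], 0.094),
        (["gemcitabine"], 0.12),
        (["gemcitabine", "cisplatin"], 0.064),
        (["capecitabine"], 0.20),
        (["bevacizumab", "paclitaxel"], 0.15),
        (["doxorubicin", "cyclophosphamide"], 0.122),
    ],
    "met_lot3": [
        (["capecitabine"], 0.215),
        (["gemcitabine"], 0.154),
        (["paclitaxel"], 0.20),
        (["docetaxel"], 0.15),
        (["carboplatin"], 0.10),
        (["doxorubicin", "cyclophosphamide"], 0.181),
    ],
}

DEFAULT_EVENT_RATES_PPPM: dict[str, dict[str, float]] = {
    "early_locally_advanced": {
        "er_visit": 0.25,
        "outpatient_visit": 0.37,
        "procedure": 23.15,
        "inpatient_admission": 0.23,
    },
    "metastatic": {
        "er_visit": 0.60,
        "outpatient_visit": 0.66,
        "procedure": 34.60,
        "inpatient_admission": 0.38,
    },
}

#: per-claim nominal-BRL gamma (shape, scale); means chosen so cohort-level
#: PPPM costs land near the magnitudes reported for this kind of cohort
DEFAULT_COST_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "procedure": (2.0, 405.0),
    "outpatient_visit": (2.0, 75.0),
    "er_visit": (2.0, 150.0),
    "inpatient_admission": (1.5, 8000.0),
    "surgery": (3.0, 2500.0),
    "drug": (2.0, 1500.0),
    "radiotherapy": (2.0, 400.0),
}


class SimulationConfig(BaseModel):
    """Study conditions for the generator; defaults mirror the cohort the
    analysis is designed for (82.8% early-stage mix, Table-2-like event
    rates, 21-day cycles)."""

    n_patients: int = Field(ge=0)
    seed: int = 0
    stage_mix: float = Field(default=0.828, ge=0, le=1)
    surgery_prob_early: float = Field(default=0.416, ge=0, le=1)
    surgery_prob_met: float = Field(default=0.374, ge=0, le=1)
    nat_prob_met_surgery: float = Field(default=0.399, ge=0, le=1)
    setting_probs: dict[str, float] = Field(
        default_factory=lambda: {"AT_only": 0.753, "NAT_only": 0.075, "NAT_AT": 0.171}
    )
    sequential_prob_at: float = Field(default=0.573, ge=0, le=1)
    sequential_prob_nat_at: float = Field(default=0.13, ge=0, le=1)
    progression_prob_early: float = Field(default=0.044, ge=0, le=1)
    lot2_prob: float = Field(default=0.484, ge=0, le=1)
    lot3_prob: float = Field(default=0.126, ge=0, le=1)
    radiotherapy_prob: float = Field(default=0.059, ge=0, le=1)
    regimen_menu: dict[str, Menu] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_REGIMEN_MENUS.items()}
    )
    cycle_interval_days: int = Field(default=21, gt=0)
    cycles_min: int = Field(default=3, ge=3)
    cycles_max: int = Field(default=6, ge=3)
    event_rates_pppm: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_EVENT_RATES_PPPM.items()
        }
    )
    cost_distributions: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_COST_DISTRIBUTIONS)
    )
    contaminant_fractions: dict[str, float] = Field(
        default_factory=lambda: {
            "screening_only": 0.0,
            "hormone_therapy_user": 0.0,
            "pre2012_activity": 0.0,
        }
    )
    study_window: tuple[date, date] = (date(2012, 1, 1), date(2017, 12, 31))

    @field_validator("event_rates_pppm")
    @classmethod
    def _rates_positive(cls, v):
        for stage, rates in v.items():
            for name, r in rates.items():
                if r <= 0:
                    raise ValueError(f"event rate {stage}/{name} must be positive")
        return v

    @field_validator("cost_distributions")
    @classmethod
    def _gamma_positive(cls, v):
        for name, (shape, scale) in v.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"gamma parameters for {name} must be positive")
        return v

    @model_validator(mode="after")
    def _check(self):
        for key, menu in self.regimen_menu.items():
            total = sum(p for _, p in menu)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"menu {key!r} probabilities sum to {total}, not 1")
        if self.cycles_max < self.cycles_min:
            raise ValueError("cycles_max < cycles_min")
        if sum(self.contaminant_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("contaminant fractions sum above 1")
        return self


@dataclass(slots=True)
class TruthLine:
    line_index: int
    molecules: frozenset[str]
    start_date: date
    end_date: date


@dataclass(slots=True)
class TruthRecord:
    patient_id: str
    true_stage: str  # "early_locally_advanced" | "metastatic"
    is_contaminant: bool = False
    contaminant_kind: str = ""
    true_setting: str = "none"  # NAT_only | AT_only | NAT_AT | none
    surgery_date: date | None = None
    lines: list[TruthLine] = field(default_factory=list)
    sequential_tags: list[str] = field(default_factory=list)
    progression_flag: bool = False


@dataclass
class GroundTruth:
    """Per-patient simulated truth enabling recovery tests."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.records.values():
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "true_stage": t.true_stage,
                    "is_contaminant": t.is_contaminant,
                    "contaminant_kind": t.contaminant_kind,
                    "true_setting": t.true_setting,
                    "surgery_date": t.surgery_date.isoformat() if t.surgery_date else "",
                    "n_lines": len(t.lines),
                    "line_starts": ";".join(l.start_date.isoformat() for l in t.lines),
                    "line_ends": ";".join(l.end_date.isoformat() for l in t.lines),
                    "progression_flag": t.progression_flag,
                }
            )
        return pd.DataFrame(rows)


def _pick(rng: np.random.Generator, menu: Menu) -> frozenset[str]:
    probs = np.array([p for _, p in menu], dtype=float)
    probs /= probs.sum()
    i = rng.choice(len(menu), p=probs)
    return frozenset(menu[i][0])


def _pick_disjoint(
    rng: np.random.Generator, menu: Menu, used: frozenset[str]
) -> frozenset[str] | None:
    options = [(m, p) for m, p in menu if not (set(m) & used)]
    if not options:
        return None
    return _pick(rng, options)


@dataclass(slots=True)
class _PlannedLine:
    molecules: frozenset[str]
    start: date
    n_cycles: int
    interval: int

    @property
    def end(self) -> date:
        return self.start + timedelta(days=(self.n_cycles - 1) * self.interval)


class _PatientBuilder:
    """Assembles one patient's claims from a treatment plan."""

    def __init__(self, pid: str, cfg: SimulationConfig, rng: np.random.Generator):
        self.pid = pid
        self.cfg = cfg
        self.rng = rng
        self.claims: list[ClaimRecord] = []

    def _cost(self, category: str) -> float:
        shape, scale = self.cfg.cost_distributions[category]
        return float(self.rng.gamma(shape, scale))

    def add(self, day: date, category: ClaimCategory, code: str = "",
            setting: CareSetting = CareSetting.OUTPATIENT,
            cost: float = 0.0, admission_days: int = 0) -> None:
        self.claims.append(
            ClaimRecord(
                patient_id=self.pid,
                service_date=day,
                category=category,
                code=code,
                setting=setting,
                cost_brl_nominal=round(cost, 2),
                admission_days=admission_days,
            )
        )

    def add_diagnosis(self, day: date, code: str) -> None:
        self.add(day, ClaimCategory.DIAGNOSIS, code)

    def add_line_claims(self, line: _PlannedLine) -> None:
        for k in range(line.n_cycles):
            day = line.start + timedelta(days=k * line.interval)
            for mol in sorted(line.molecules):
                self.add(day, ClaimCategory.DRUG, mol, cost=self._cost("drug"))

    def add_surgery(self, day: date) -> None:
        self.add(
            day,
            ClaimCategory.SURGERY,
            "BREAST-SURGERY",
            setting=CareSetting.INPATIENT,
            cost=self._cost("surgery"),
        )

    def add_events(self, lines: list[_PlannedLine], stage: str) -> None:
        """Poisson events over treatment periods at the configured PPPM rates.

        Counts are drawn as Poisson(rate x line-months) per line — by Poisson
        additivity identical in law to month-by-month draws — with event days
        uniform inside the line interval.
        """
        rates = self.cfg.event_rates_pppm[stage]
        for line in lines:
            span_days = (line.end - line.start).days
            months = span_days / 30.4375
            for name, rate in rates.items():
                n = int(self.rng.poisson(rate * months))
                if n == 0:
                    continue
                offsets = self.rng.integers(0, span_days + 1, size=n)
                category = ClaimCategory(name)
                for off in offsets:
                    day = line.start + timedelta(days=int(off))
                    if category is ClaimCategory.INPATIENT_ADMISSION:
                        self.add(
                            day, category, "ADMISSION",
                            setting=CareSetting.INPATIENT,
                            cost=self._cost(name),
                            admission_days=int(self.rng.poisson(2.0)) + 1,
                        )
                    else:
                        self.add(day, category, name.upper(), cost=self._cost(name))
        if self.rng.random() < self.cfg.radiotherapy_prob and lines:
            line = lines[-1]
            off = int(self.rng.integers(0, (line.end - line.start).days + 1))
            self.add(
                line.start + timedelta(days=off),
                ClaimCategory.RADIOTHERAPY,
                "RADIOTHERAPY",
                cost=self._cost("radiotherapy"),
            )


def _rand_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _u(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _simulate_patient(
    idx: int, cfg: SimulationConfig, seed_seq: np.random.SeedSequence
) -> tuple[PatientRecord, TruthRecord]:
    rng = np.random.default_rng(seed_seq)
    pid = f"P{idx:06d}"
    b = _PatientBuilder(pid, cfg, rng)
    truth = TruthRecord(patient_id=pid, true_stage="early_locally_advanced")

    # contaminant assignment: cumulative thresholds over the unit interval
    u = rng.random()
    acc = 0.0
    kind = ""
    for k, frac in cfg.contaminant_fractions.items():
        acc += frac
        if u < acc:
            kind = k
            break

    win_lo, win_hi = cfg.study_window
    index_lo = max(win_lo + timedelta(days=60), win_lo)
    index_hi = win_hi - timedelta(days=550)
    index_date = _rand_date(rng, index_lo, index_hi)
    age = _u(rng, 25, 80)
    region = Region.SOUTHEAST if rng.random() < 0.685 else Region(
        ["North", "Northeast", "Central-West", "South"][_u(rng, 0, 3)]
    )

    if kind == "screening_only":
        # a C50 coded for screening purposes, never any systemic treatment
        b.add_diagnosis(index_date, "C50.9")
        b.add(index_date, ClaimCategory.OUTPATIENT_VISIT, "OUTPATIENT_VISIT",
              cost=b._cost("outpatient_visit"))
        truth.is_contaminant, truth.contaminant_kind = True, kind
        return _finish(b, truth, age, region)

    early = rng.random() < cfg.stage_mix
    truth.true_stage = "early_locally_advanced" if early else "metastatic"

    b.add_diagnosis(index_date, "C50.9")
    if not early:
        # stage evidence: two distant-metastasis codes >= 15 days apart
        # inside the staging window
        b.add_diagnosis(index_date + timedelta(days=10), "C78.0")
        b.add_diagnosis(index_date + timedelta(days=40), "C79.5")

    menus = cfg.regimen_menu
    interval = cfg.cycle_interval_days

    def n_cycles() -> int:
        return _u(rng, cfg.cycles_min, cfg.cycles_max)

    planned: list[_PlannedLine] = []
    surgery_date: date | None = None

    def append_line(mols: frozenset[str], start: date) -> _PlannedLine:
        line = _PlannedLine(mols, start, n_cycles(), interval)
        planned.append(line)
        return line

    def follow_on(menu_key: str, prev: _PlannedLine, gap_lo: int, gap_hi: int
                  ) -> _PlannedLine | None:
        """Plan a next line the LOT rules will recover: a molecule-disjoint
        regimen after a sub-120-day gap (switch rule), or any regimen after a
        120+-day gap (gap rule) when no disjoint option exists."""
        mols = _pick_disjoint(rng, menus[menu_key], prev.molecules)
        if mols is None:
            mols = _pick(rng, menus[menu_key])
            start = prev.end + timedelta(days=_u(rng, 120, 160))
        else:
            start = prev.end + timedelta(days=_u(rng, max(gap_lo, 18), gap_hi))
        return append_line(mols, start)

    if early:
        if rng.random() < cfg.surgery_prob_early:
            probs = cfg.setting_probs
            names = list(probs)
            weights = np.array([probs[n] for n in names], dtype=float)
            setting = names[rng.choice(len(names), p=weights / weights.sum())]
            truth.true_setting = setting
            if setting == "AT_only":
                surgery_date = index_date + timedelta(days=_u(rng, 14, 45))
                at = append_line(
                    _pick(rng, menus["early_at"]),
                    surgery_date + timedelta(days=_u(rng, 30, 60)),
                )
                if rng.random() < cfg.sequential_prob_at:
                    follow_on("early_seq", at, 18, 45)
            elif setting == "NAT_only":
                nat = append_line(
                    _pick(rng, menus["early_nat"]),
                    index_date + timedelta(days=_u(rng, 5, 20)),
                )
                surgery_date = nat.end + timedelta(days=_u(rng, 10, 40))
            else:  # NAT_AT
                nat = append_line(
                    _pick(rng, menus["early_nat"]),
                    index_date + timedelta(days=_u(rng, 5, 20)),
                )
                sequential = rng.random() < cfg.sequential_prob_nat_at
                if sequential:
                    surgery_date = nat.end + timedelta(days=_u(rng, 10, 20))
                    at_start = surgery_date + timedelta(days=_u(rng, 10, 25))
                else:
                    surgery_date = nat.end + timedelta(days=_u(rng, 20, 40))
                    at_start = surgery_date + timedelta(days=_u(rng, 26, 70))
                mols = _pick_disjoint(rng, menus["early_seq"], nat.molecules)
                if mols is None:
                    mols = frozenset({"paclitaxel"}) - nat.molecules or frozenset(
                        {"capecitabine"}
                    )
                append_line(mols, at_start)
            if planned and rng.random() < cfg.progression_prob_early:
                prev = planned[-1]
                mols = _pick_disjoint(
                    rng,
                    [(["gemcitabine"], 0.5), (["capecitabine"], 0.5)],
                    prev.molecules,
                )
                if mols is not None:
                    extra = append_line(
                        mols, prev.end + timedelta(days=_u(rng, 46, 110))
                    )
                    # the progression regimen starts post-surgery, so a
                    # NAT-only patient becomes NAT+AT under the setting rule
                    if (
                        truth.true_setting == "NAT_only"
                        and surgery_date is not None
                        and extra.start >= surgery_date
                    ):
                        truth.true_setting = "NAT_AT"
        else:
            append_line(
                _pick(rng, menus["early_at"]),
                index_date + timedelta(days=_u(rng, 7, 30)),
            )
    else:  # metastatic
        has_surgery = rng.random() < cfg.surgery_prob_met
        nat = has_surgery and rng.random() < cfg.nat_prob_met_surgery
        if nat:
            line1 = append_line(
                _pick(rng, menus["met_nat"]),
                index_date + timedelta(days=_u(rng, 5, 20)),
            )
            surgery_date = line1.end + timedelta(days=_u(rng, 10, 40))
            truth.true_setting = "NAT_only"
        else:
            if has_surgery:
                surgery_date = index_date + timedelta(days=_u(rng, 5, 25))
                start = surgery_date + timedelta(days=_u(rng, 10, 40))
            else:
                start = index_date + timedelta(days=_u(rng, 7, 45))
            line1 = append_line(_pick(rng, menus["met_lot1"]), start)
        if rng.random() < cfg.lot2_prob:
            lot2 = follow_on("met_lot2", planned[-1], 18, 60)
            if lot2 is not None and rng.random() < cfg.lot3_prob:
                follow_on("met_lot3", lot2, 18, 60)

    for line in planned:
        b.add_line_claims(line)
    if surgery_date is not None:
        b.add_surgery(surgery_date)
        truth.surgery_date = surgery_date
    b.add_events(planned, truth.true_stage)

    truth.lines = [
        TruthLine(i + 1, ln.molecules, ln.start, ln.end)
        for i, ln in enumerate(planned)
    ]
    tags = ["initial"]
    for prev, nxt in zip(planned, planned[1:]):
        gap = (nxt.start - prev.end).days
        tags.append("sequential" if gap <= 45 else "progressive_disease")
    truth.sequential_tags = tags[: len(planned)]
    truth.progression_flag = early and "progressive_disease" in truth.sequential_tags

    if kind == "hormone_therapy_user":
        # otherwise-valid patient disqualified solely by a hormone-therapy claim
        b.add(index_date + timedelta(days=_u(rng, 30, 200)), ClaimCategory.DRUG,
              "tamoxifen", cost=b._cost("drug"))
        truth.is_contaminant, truth.contaminant_kind = True, kind
    elif kind == "pre2012_activity":
        # otherwise-valid patient with washout-period disease activity
        b.add_diagnosis(date(2011, 1, 1) + timedelta(days=_u(rng, 0, 360)), "C50.9")
        truth.is_contaminant, truth.contaminant_kind = True, kind

    return _finish(b, truth, age, region)


def _finish(
    b: _PatientBuilder, truth: TruthRecord, age: int, region: Region
) -> tuple[PatientRecord, TruthRecord]:
    b.claims.sort(key=lambda c: c.service_date)
    patient = PatientRecord(
        patient_id=b.pid, age_at_first_claim=age, region=region, claims=b.claims
    )
    return patient, truth


def simulate(config: SimulationConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a claims cohort plus its ground truth, deterministically.

    Returns patients sorted by id.  ``n_patients = 0`` yields empty outputs.
    """
    base = abs(int(config.seed)) % (2**31)
    patients: list[PatientRecord] = []
    truth = GroundTruth()
    for i in range(config.n_patients):
        p, t = _simulate_patient(i, config, np.random.SeedSequence((base, i)))
        patients.append(p)
        truth.records[p.patient_id] = t
    return patients, truth


# --------------------------------------------------------------------------
# canned hand-specified fixtures with documented downstream labels
# --------------------------------------------------------------------------

_ANCHOR = date(2013, 4, 1)


def _fx_claim(pid, days, category, code, **kw):
    return ClaimRecord(
        patient_id=pid,
        service_date=_ANCHOR + timedelta(days=days),
        category=category,
        code=code,
        **kw,
    )


def _fixture_switch_day70() -> list[PatientRecord]:
    """AC on days 0/21/42, paclitaxel on day 70 -> two lines (switch rule)."""
    pid = "FX-SWITCH70"
    claims = [_fx_claim(pid, 0, ClaimCategory.DIAGNOSIS, "C50.9")]
    for d in (0, 21, 42):
        claims += [
            _fx_claim(pid, d, ClaimCategory.DRUG, "doxorubicin"),
            _fx_claim(pid, d, ClaimCategory.DRUG, "cyclophosphamide"),
        ]
    claims.append(_fx_claim(pid, 70, ClaimCategory.DRUG, "paclitaxel"))
    return [PatientRecord(patient_id=pid, age_at_first_claim=48, claims=claims)]


def _fixture_gap_130() -> list[PatientRecord]:
    """Paclitaxel day 0 and day 130 -> two lines (120-day gap rule)."""
    pid = "FX-GAP130"
    claims = [
        _fx_claim(pid, 0, ClaimCategory.DIAGNOSIS, "C50.1"),
        _fx_claim(pid, 0, ClaimCategory.DRUG, "paclitaxel"),
        _fx_claim(pid, 130, ClaimCategory.DRUG, "paclitaxel"),
    ]
    return [PatientRecord(patient_id=pid, age_at_first_claim=55, claims=claims)]


def _fixture_sequential_27d() -> list[PatientRecord]:
    """AC ending day 63, paclitaxel from day 90 (27-day gap) -> sequential."""
    pid = "FX-SEQ27"
    claims = [_fx_claim(pid, -10, ClaimCategory.DIAGNOSIS, "C50.9")]
    for d in (0, 21, 42, 63):
        claims += [
            _fx_claim(pid, d, ClaimCategory.DRUG, "doxorubicin"),
            _fx_claim(pid, d, ClaimCategory.DRUG, "cyclophosphamide"),
        ]
    for d in (90, 111):
        claims.append(_fx_claim(pid, d, ClaimCategory.DRUG, "paclitaxel"))
    return [PatientRecord(patient_id=pid, age_at_first_claim=61, claims=claims)]


def _fixture_met_two_c78() -> list[PatientRecord]:
    """Two C78 claims at index+10 / index+40 -> metastatic."""
    pid = "FX-MET-C78"
    claims = [
        _fx_claim(pid, 0, ClaimCategory.DIAGNOSIS, "C50.9"),
        _fx_claim(pid, 10, ClaimCategory.DIAGNOSIS, "C78.0"),
        _fx_claim(pid, 40, ClaimCategory.DIAGNOSIS, "C78.0"),
        _fx_claim(pid, 15, ClaimCategory.DRUG, "paclitaxel"),
    ]
    return [PatientRecord(patient_id=pid, age_at_first_claim=50, claims=claims)]


def _fixture_c773_only() -> list[PatientRecord]:
    """Only C77.3 metastatic-range codes -> stays early/locally advanced."""
    pid = "FX-C773"
    claims = [
        _fx_claim(pid, 0, ClaimCategory.DIAGNOSIS, "C50.9"),
        _fx_claim(pid, 10, ClaimCategory.DIAGNOSIS, "C77.3"),
        _fx_claim(pid, 40, ClaimCategory.DIAGNOSIS, "C77.3"),
        _fx_claim(pid, 15, ClaimCategory.DRUG, "docetaxel"),
    ]
    return [PatientRecord(patient_id=pid, age_at_first_claim=47, claims=claims)]


def _fixture_hormone_user() -> list[PatientRecord]:
    """Tamoxifen claim -> excluded by the exclusion-molecule rule."""
    pid = "FX-HORMONE"
    claims = [
        _fx_claim(pid, 0, ClaimCategory.DIAGNOSIS, "C50.9"),
        _fx_claim(pid, 15, ClaimCategory.DRUG, "docetaxel"),
        _fx_claim(pid, 60, ClaimCategory.DRUG, "tamoxifen"),
    ]
    return [PatientRecord(patient_id=pid, age_at_first_claim=52, claims=claims)]


def _fixture_pre2012() -> list[PatientRecord]:
    """C50 claim in 2011 -> excluded by the washout rule."""
    pid = "FX-PRE2012"
    claims = [
        ClaimRecord(pid, date(2011, 6, 1), ClaimCategory.DIAGNOSIS, "C50.9"),
        _fx_claim(pid, 0, ClaimCategory.DIAGNOSIS, "C50.9"),
        _fx_claim(pid, 20, ClaimCategory.DRUG, "doxorubicin"),
    ]
    return [PatientRecord(patient_id=pid, age_at_first_claim=44, claims=claims)]


FIXTURES = {
    "switch_day70": _fixture_switch_day70,
    "gap_130": _fixture_gap_130,
    "sequential_27d": _fixture_sequential_27d,
    "met_two_c78": _fixture_met_two_c78,
    "c773_only": _fixture_c773_only,
    "hormone_user": _fixture_hormone_user,
    "pre2012": _fixture_pre2012,
}


def make_fixture(name: str) -> list[PatientRecord]:
    """A tiny hand-specified patient set with documented downstream labels."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)}"
        ) from None
    return factory()
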