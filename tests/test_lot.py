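"""Line-of-therapy construction: rule examples, exhaustive oracle
equivalence over the critical day offsets, setting classification, and
sequential/progression tagging."""

from __future__ import annotations

from datetime import date, timedelta
from itertools import combinations_with_replacement, product

import pytest

from tnbc_claims import (
    ClaimCategory,
    ClaimRecord,
    LineTrigger,
    PatientRecord,
    RegimenTag,
    TreatmentSetting,
    build_lines,
    classify_setting,
    inclusion_drug_claims,
    make_fixture,
    tag_sequential_or_progression,
    transition_matrix,
)
from tnbc_claims.lot import Regimen

DAY0 = date(2014, 1, 1)


def _drug(day: int, mol: str, pid="p") -> ClaimRecord:
    return ClaimRecord(pid, DAY0 + timedelta(days=day), ClaimCategory.DRUG, mol)


def replay_oracle(claims):
    """Independent step-by-step replay of the line rules.

    Returns a list of (start day, claim indices, molecule set, trigger) per
    line, applying: 120-day gap from the previous claim first, then the
    60-day switch from the line start for molecules outside the current
    regimen; everything else joins the current line.
    """
    lines, cur = [], None
    for i, c in enumerate(claims):
        day = (c.service_date - DAY0).days
        mol = c.code
        if cur is None:
            cur = dict(start=day, idx=[i], mols={mol}, last=day, trig="initiation")
        elif day - cur["last"] >= 120:
            lines.append(cur)
            cur = dict(start=day, idx=[i], mols={mol}, last=day, trig="gap_120d")
        elif mol not in cur["mols"] and day - cur["start"] >= 60:
            lines.append(cur)
            cur = dict(start=day, idx=[i], mols={mol}, last=day, trig="switch_60d")
        else:
            cur["idx"].append(i)
            cur["mols"].add(mol)
            cur["last"] = day
    if cur is not None:
        lines.append(cur)
    return lines


def _as_tuples(lines):
    return [
        (
            (ln.start_date - DAY0).days,
            (ln.end_date - DAY0).days,
            set(ln.molecules),
            ln.start_trigger.value,
        )
        for ln in lines
    ]


class TestRuleExamples:
    def test_ac_then_taxane_switch(self, catalog):
        claims = (
            [_drug(d, "doxorubicin") for d in (0, 21, 42)]
            + [_drug(d, "cyclophosphamide") for d in (0, 21, 42)]
            + [_drug(70, "paclitaxel")]
        )
        claims.sort(key=lambda c: c.service_date)
        lines = build_lines(claims, catalog)
        assert _as_tuples(lines) == [
            (0, 42, {"doxorubicin", "cyclophosphamide"}, "initiation"),
            (70, 70, {"paclitaxel"}, "switch_60d"),
        ]
        assert lines[0].label == "AC"

    def test_120_day_gap_same_molecule(self, catalog):
        lines = build_lines([_drug(0, "paclitaxel"), _drug(130, "paclitaxel")], catalog)
        assert len(lines) == 2
        assert lines[1].start_trigger is LineTrigger.GAP_120D

    def test_concurrent_molecules_form_one_regimen(self, catalog):
        lines = build_lines(
            [_drug(0, "doxorubicin"), _drug(14, "cyclophosphamide")], catalog
        )
        assert len(lines) == 1
        assert lines[0].molecules == {"doxorubicin", "cyclophosphamide"}

    def test_new_molecule_before_day_60_extends_regimen(self, catalog):
        lines = build_lines([_drug(0, "carboplatin"), _drug(50, "gemcitabine")], catalog)
        assert len(lines) == 1
        assert lines[0].molecules == {"carboplatin", "gemcitabine"}

    def test_empty_input(self, catalog):
        assert build_lines([], catalog) == []

    def test_multiple_patients_rejected(self, catalog):
        with pytest.raises(ValueError):
            build_lines([_drug(0, "paclitaxel", "a"), _drug(1, "paclitaxel", "b")])

    def test_fixture_switch_day70(self, catalog):
        (p,) = make_fixture("switch_day70")
        lines = build_lines(inclusion_drug_claims(p.claims, catalog), catalog)
        assert [ln.label for ln in lines] == ["AC", "paclitaxel"]

    def test_fixture_gap_130(self, catalog):
        (p,) = make_fixture("gap_130")
        lines = build_lines(inclusion_drug_claims(p.claims, catalog), catalog)
        assert [ln.start_trigger for ln in lines] == [
            LineTrigger.INITIATION,
            LineTrigger.GAP_120D,
        ]


CRITICAL_OFFSETS = (0, 14, 28, 45, 46, 59, 60, 61, 119, 120, 121)


def test_exhaustive_oracle_equivalence(catalog):
    """All claim sequences of up to 4 claims over two molecules with days
    drawn from the offsets bracketing the 45/60/120-day thresholds match the
    independent replay oracle (boundaries, claim partition, triggers)."""
    checked = 0
    for n in range(1, 5):
        for days in combinations_with_replacement(CRITICAL_OFFSETS, n):
            for mols in product("ab", repeat=n):
                claims = [_drug(d, m) for d, m in zip(days, mols)]
                pos = {id(c): i for i, c in enumerate(claims)}
                lines = build_lines(claims, catalog)
                expected = replay_oracle(claims)
                got = [
                    (
                        (ln.start_date - DAY0).days,
                        [pos[id(c)] for c in ln.claims],
                        set(ln.molecules),
                        ln.start_trigger.value,
                    )
                    for ln in lines
                ]
                want = [
                    (o["start"], o["idx"], o["mols"], o["trig"]) for o in expected
                ]
                assert got == want, (days, mols)
                checked += 1
    assert checked > 10_000


def test_partition_invariants_on_simulated_patients(clean_cohort, catalog):
    """Line starts strictly increase; every drug claim lands in exactly one
    line; no claim is lost."""
    patients, _ = clean_cohort
    for p in patients[:200]:
        claims = inclusion_drug_claims(p.claims, catalog)
        lines = build_lines(claims, catalog)
        starts = [ln.start_date for ln in lines]
        assert starts == sorted(starts) and len(set(starts)) == len(starts)
        assigned = [c for ln in lines for c in ln.claims]
        assert len(assigned) == len(claims)
        assert {id(c) for c in assigned} == {id(c) for c in claims}
        for ln in lines:
            assert ln.start_date <= ln.end_date
            assert ln.end_date == ln.claims[-1].service_date


def test_line_recovery_against_ground_truth(clean_cohort, catalog):
    """On a noise-free cohort the builder reproduces the planted line count,
    boundaries and molecule sets for at least 99% of patients."""
    patients, truth = clean_cohort
    ok = 0
    for p in patients:
        lines = build_lines(inclusion_drug_claims(p.claims, catalog), catalog)
        got = [(ln.start_date, ln.end_date, ln.molecules) for ln in lines]
        want = [(t.start_date, t.end_date, t.molecules) for t in truth.records[p.patient_id].lines]
        ok += got == want
    assert ok / len(patients) >= 0.99


class TestSettingClassification:
    def _lines(self, catalog, specs):
        claims = [_drug(d, m) for d, m in specs]
        return build_lines(claims, catalog)

    def test_nat_at(self, catalog):
        surgery = DAY0 + timedelta(days=0)
        lines = self._lines(
            catalog,
            [(-60, "doxorubicin"), (-39, "doxorubicin"), (-18, "doxorubicin"),
             (30, "paclitaxel"), (51, "paclitaxel")],
        )
        sa = classify_setting("p", lines, surgery)
        assert sa.setting is TreatmentSetting.NAT_AT

    def test_at_only_and_nat_only(self, catalog):
        lines = self._lines(catalog, [(30, "paclitaxel"), (51, "paclitaxel")])
        assert classify_setting("p", lines, DAY0).setting is TreatmentSetting.AT_ONLY
        lines = self._lines(catalog, [(-60, "paclitaxel"), (-39, "paclitaxel")])
        assert classify_setting("p", lines, DAY0).setting is TreatmentSetting.NAT_ONLY

    def test_missing_surgery_date_is_error(self, catalog):
        with pytest.raises(ValueError):
            classify_setting("p", [], None)

    def test_recovery_against_ground_truth(self, clean_cohort, catalog):
        patients, truth = clean_cohort
        for p in patients:
            t = truth.records[p.patient_id]
            if t.surgery_date is None or t.true_stage != "early_locally_advanced":
                continue
            lines = build_lines(inclusion_drug_claims(p.claims, catalog), catalog)
            sa = classify_setting(p.patient_id, lines, t.surgery_date)
            assert sa.setting.value == t.true_setting, p.patient_id


class TestSequentialProgression:
    def _regimen(self, start, end, mols=("paclitaxel",)):
        return Regimen(
            molecules=frozenset(mols),
            label="+".join(sorted(mols)),
            start_date=DAY0 + timedelta(days=start),
            end_date=DAY0 + timedelta(days=end),
        )

    def test_gap_27_is_sequential(self):
        tags, flag = tag_sequential_or_progression(
            [self._regimen(0, 63, ("doxorubicin", "cyclophosphamide")),
             self._regimen(90, 111)]
        )
        assert tags == [RegimenTag.INITIAL, RegimenTag.SEQUENTIAL]
        assert not flag

    def test_gap_67_is_progressive_disease(self):
        tags, flag = tag_sequential_or_progression(
            [self._regimen(0, 63, ("doxorubicin", "cyclophosphamide")),
             self._regimen(130, 151)]
        )
        assert tags[-1] is RegimenTag.PROGRESSIVE_DISEASE
        assert flag

    def test_boundary_gap_45_vs_46(self):
        seq, _ = tag_sequential_or_progression(
            [self._regimen(0, 42, ("doxorubicin",)), self._regimen(87, 108)]
        )
        prog, flag = tag_sequential_or_progression(
            [self._regimen(0, 42, ("doxorubicin",)), self._regimen(88, 109)]
        )
        assert seq[-1] is RegimenTag.SEQUENTIAL
        assert prog[-1] is RegimenTag.PROGRESSIVE_DISEASE and flag

    def test_single_regimen_untouched(self):
        tags, flag = tag_sequential_or_progression([self._regimen(0, 42)])
        assert tags == [RegimenTag.INITIAL] and not flag

    def test_fixture_sequential_27d(self, catalog):
        (p,) = make_fixture("sequential_27d")
        lines = build_lines(inclusion_drug_claims(p.claims, catalog), catalog)
        regimens = [r for ln in lines for r in ln.regimens]
        tags, flag = tag_sequential_or_progression(regimens)
        assert tags == [RegimenTag.INITIAL, RegimenTag.SEQUENTIAL] and not flag


class TestTransitionMatrix:
    def _lines(self, catalog, *mol_seqs):
        out = {}
        for i, seq in enumerate(mol_seqs):
            claims = []
            day = 0
            for mols in seq:
                claims += [_drug(day, m, f"p{i}") for m in mols]
                claims += [_drug(day + 21, m, f"p{i}") for m in mols]
                claims += [_drug(day + 42, m, f"p{i}") for m in mols]
                day += 200
            out[f"p{i}"] = build_lines(claims, catalog)
        return out

    def test_counting(self, catalog):
        AC = ("doxorubicin", "cyclophosphamide")
        lines = self._lines(
            catalog,
            [AC, ("paclitaxel",)],
            [AC, ("paclitaxel",)],
            [AC, ("docetaxel",)],
        )
        m = transition_matrix(lines)
        assert m == {("AC", "paclitaxel"): 2, ("AC", "docetaxel"): 1}

    def test_single_regimen_patients_give_empty_matrix(self, catalog):
        lines = self._lines(catalog, [("paclitaxel",)], [("docetaxel",)])
        assert transition_matrix(lines) == {}

    def test_total_count_conservation(self, clean_cohort, catalog):
        patients, _ = clean_cohort
        lines = {
            p.patient_id: build_lines(
                inclusion_drug_claims(p.claims, catalog), catalog
            )
            for p in patients[:150]
        }
        m = transition_matrix(lines)
        n_regimens = sum(len([r for ln in lns for r in ln.regimens]) for lns in lines.values())
        n_with_any = sum(1 for lns in lines.values() if lns)
        assert sum(m.values()) == n_regimens - n_with_any
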