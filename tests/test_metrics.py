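"""Durations, PPPM estimates with Poisson/gamma intervals, and the currency
chain."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tnbc_claims import (
    CareSetting,
    ClaimCategory,
    ClaimRecord,
    CurrencyParameters,
    MonthConvention,
    adjust_and_convert,
    aggregate_costs,
    build_lines,
    months_between,
    poisson_exact_ci,
    pppm_cost,
    pppm_count,
    restrict_to_treatment_periods,
    summarize,
    treatment_duration,
    ttnt,
)

D0 = date(2014, 1, 1)


def _drug(day, mol="paclitaxel"):
    return ClaimRecord("p", D0 + timedelta(days=day), ClaimCategory.DRUG, mol)


def _ev(day, cat=ClaimCategory.PROCEDURE, cost=0.0):
    setting = (
        CareSetting.INPATIENT
        if cat in (ClaimCategory.INPATIENT_ADMISSION, ClaimCategory.SURGERY)
        else CareSetting.OUTPATIENT
    )
    return ClaimRecord("p", D0 + timedelta(days=day), cat, "X", setting=setting,
                       cost_brl_nominal=cost)


class TestMonths:
    @pytest.mark.parametrize(
        "days,expected", [(0, 0.0), (70, 2.30), (183, 6.01), (28, 0.92)]
    )
    def test_day_to_month_conversion(self, days, expected):
        got = months_between(D0, D0 + timedelta(days=days))
        assert got == pytest.approx(days / 30.4375)
        assert round(got, 2) == expected

    def test_out_of_order_dates_rejected(self):
        with pytest.raises(ValueError):
            months_between(D0 + timedelta(days=1), D0)

    def test_custom_convention(self):
        got = months_between(D0, D0 + timedelta(days=60), MonthConvention(30.0))
        assert got == pytest.approx(2.0)


class TestDurationAndTTNT:
    def test_line_duration_endpoints_only(self, catalog):
        lines = build_lines([_drug(0), _drug(35), _drug(71)], catalog)
        assert treatment_duration(lines[0]) == pytest.approx(71 / 30.4375)
        # claims strictly inside the span do not move the endpoints
        lines2 = build_lines([_drug(0), _drug(20), _drug(35), _drug(71)], catalog)
        assert treatment_duration(lines2[0]) == treatment_duration(lines[0])

    def test_single_claim_line_has_zero_duration(self, catalog):
        (line,) = build_lines([_drug(0)], catalog)
        assert treatment_duration(line) == 0.0

    def test_ttnt_between_line_starts(self, catalog):
        l1, l2 = build_lines([_drug(0), _drug(130)], catalog)
        assert ttnt(l1, l2) == pytest.approx(130 / 30.4375)
        with pytest.raises(ValueError):
            ttnt(l2, l1)


class TestSummarize:
    def test_quartiles_by_linear_interpolation(self):
        s = summarize([1, 2, 3, 4])
        assert (s.median, s.iqi_low, s.iqi_high) == (2.5, 1.75, 3.25)
        assert s.mean == 2.5
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_value_convention(self):
        s = summarize([5])
        assert (s.n, s.mean, s.sd, s.median, s.iqi_low, s.iqi_high) == (
            1, 5, 0.0, 5, 5, 5,
        )

    def test_constant_list_degenerates(self):
        s = summarize([3.0] * 10)
        assert s.sd == 0.0 and s.iqi_low == s.iqi_high == 3.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestTreatmentPeriodRestriction:
    def test_between_line_claims_dropped_boundaries_kept(self, catalog):
        lines = build_lines([_drug(0), _drug(42), _drug(200), _drug(242)], catalog)
        assert len(lines) == 2
        claims = [_ev(0), _ev(42), _ev(100), _ev(200), _ev(250)]
        kept, exposure = restrict_to_treatment_periods(claims, lines)
        assert [(c.service_date - D0).days for c in kept] == [0, 42, 200]
        assert exposure == pytest.approx((42 + 42) / 30.4375)

    def test_single_day_line_gets_exposure_floor(self, catalog):
        lines = build_lines([_drug(0)], catalog)
        kept, exposure = restrict_to_treatment_periods([_ev(0), _ev(1)], lines)
        assert len(kept) == 1
        assert exposure == 0.25


class TestPoissonPPPM:
    def test_zero_events(self):
        est = pppm_count(0, 100.0, 10)
        assert est.point == 0.0 and est.ci_low == 0.0 and est.ci_high > 0

    def test_exact_interval_matches_chi_square_oracle(self):
        est = pppm_count(100, 400.0, 50)
        lo = stats.chi2.ppf(0.025, 200) / 2
        hi = stats.chi2.ppf(0.975, 202) / 2
        assert (lo, hi) == pytest.approx((81.3643, 121.6272), abs=1e-3)
        assert est.point == pytest.approx(0.25)
        assert est.ci_low == pytest.approx(lo / 400)
        assert est.ci_high == pytest.approx(hi / 400)

    def test_doubling_preserves_point_and_narrows_ci(self):
        a = pppm_count(50, 200.0, 20)
        b = pppm_count(100, 400.0, 40)
        assert a.point == b.point
        assert (b.ci_high - b.ci_low) < (a.ci_high - a.ci_low)

    def test_invalid_exposure(self):
        with pytest.raises(ValueError):
            pppm_count(5, 0.0, 1)

    def test_coverage_on_simulated_counts(self):
        """Exact Poisson intervals at rate 0.3 PPPM, 500 patients x 4 months,
        200 replicates: empirical coverage stays in [92%, 98%]."""
        rng = np.random.default_rng(2024)
        rate, exposure = 0.3, 500 * 4.0
        hit = 0
        for _ in range(200):
            count = rng.poisson(rate * exposure)
            est = pppm_count(int(count), exposure, 500)
            hit += est.ci_low <= rate <= est.ci_high
        assert 0.92 <= hit / 200 <= 0.98


class TestGammaPPPM:
    def test_constant_values_collapse(self):
        est = pppm_cost([100.0] * 50)
        assert est.point == est.ci_low == est.ci_high == 100.0

    def test_all_zero_degenerate(self):
        est = pppm_cost([0.0, 0.0, 0.0])
        assert (est.point, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_two_values_bracket_mean(self):
        est = pppm_cost([10.0, 30.0])
        assert est.ci_low <= est.point <= est.ci_high
        assert est.point == 20.0

    def test_coverage_for_gamma_distributed_costs(self):
        """Moment-matched gamma intervals on gamma(2, 500) cost data
        (true mean 1000), 100 replicates of n=200: coverage near 95%."""
        rng = np.random.default_rng(7)
        hit = 0
        for _ in range(100):
            est = pppm_cost(rng.gamma(2.0, 500.0, size=200))
            assert est.family == "gamma"
            hit += est.ci_low <= 1000.0 <= est.ci_high
        assert 0.90 <= hit / 100 <= 1.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            pppm_cost([-1.0, 2.0])


class TestCurrencyChain:
    @pytest.mark.parametrize(
        "adjusted_brl,usd",
        [(37345.27, 7351.72), (50828.22, 10005.95), (0.0, 0.0)],
    )
    def test_brl_to_usd_at_fixed_rate(self, adjusted_brl, usd):
        _, got = adjust_and_convert(adjusted_brl, already_adjusted=True)
        assert round(got, 2) == usd

    def test_inflation_then_exchange(self):
        adjusted, usd = adjust_and_convert(1000.0)
        assert adjusted == pytest.approx(1576.9934)
        assert usd == pytest.approx(1576.9934 * 0.1968581)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            adjust_and_convert(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1e6),
    )
    def test_linearity(self, a, b):
        _, ua = adjust_and_convert(a)
        _, ub = adjust_and_convert(b)
        _, uab = adjust_and_convert(a + b)
        assert uab == pytest.approx(ua + ub, abs=0.01)


class TestCostAggregation:
    def test_drug_costs_excluded_entirely(self):
        claims = [
            ClaimRecord("p", D0, ClaimCategory.DRUG, "paclitaxel",
                        cost_brl_nominal=5000.0)
        ]
        bd = aggregate_costs(claims)
        assert bd.total_brl == bd.inpatient_brl == bd.outpatient_brl == 0.0
        assert bd.medication_excluded

    def test_surgery_cost_is_inpatient_and_inflated(self):
        bd = aggregate_costs([_ev(0, ClaimCategory.SURGERY, cost=1000.0)])
        assert bd.inpatient_brl == pytest.approx(1576.9934)
        assert bd.outpatient_brl == 0.0

    def test_component_assignment(self):
        claims = [
            _ev(0, ClaimCategory.INPATIENT_ADMISSION, cost=100.0),
            _ev(1, ClaimCategory.SURGERY, cost=50.0),
            _ev(2, ClaimCategory.PROCEDURE, cost=10.0),
            _ev(3, ClaimCategory.ER_VISIT, cost=20.0),
            _ev(4, ClaimCategory.OUTPATIENT_VISIT, cost=5.0),
        ]
        bd = aggregate_costs(claims)
        f = CurrencyParameters().inflation_factor
        assert bd.inpatient_brl == pytest.approx(150 * f)
        assert bd.outpatient_brl == pytest.approx(35 * f)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(ClaimCategory)),
                st.floats(min_value=0, max_value=1e5),
            ),
            max_size=25,
        )
    )
    def test_total_is_sum_of_components(self, raw):
        claims = []
        for i, (cat, cost) in enumerate(raw):
            setting = (
                CareSetting.INPATIENT
                if cat in (ClaimCategory.INPATIENT_ADMISSION, ClaimCategory.SURGERY)
                else CareSetting.OUTPATIENT
            )
            code = "mol" if cat is ClaimCategory.DRUG else "X"
            claims.append(
                ClaimRecord("p", D0 + timedelta(days=i), cat, code,
                            setting=setting, cost_brl_nominal=cost)
            )
        bd = aggregate_costs(claims)
        assert bd.total_brl == pytest.approx(bd.inpatient_brl + bd.outpatient_brl)
        assert bd.total_usd == pytest.approx(bd.inpatient_usd + bd.outpatient_usd)
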