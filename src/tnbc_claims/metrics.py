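"""Durations, time-to-next-treatment, per-patient-per-month (PPPM) rates and
costs with 95% confidence intervals, and currency adjustment.

Conventions
-----------
* One month = 30.4375 days (365.25 / 12), used for every day→month
  conversion.
* Exposure is restricted to treatment periods: only claims dated inside a
  line of therapy count, and exposure months are the summed line durations
  (with a small floor so single-visit lines contribute nonzero exposure).
* Event rates use a pooled estimate (total events / total patient-months)
  with an exact Poisson (Garwood) interval; costs use the mean of
  per-patient PPPM values with a moment-matched gamma interval.
* Nominal BRL costs are inflation-adjusted by a single average factor and
  converted to USD at a fixed rate; medication costs are never aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
from scipy import stats

from .lot import LineOfTherapy
from .models import ClaimCategory, ClaimRecord

DAYS_PER_MONTH = 30.4375
EXPOSURE_FLOOR_MONTHS = 0.25

#: average IPCA inflation factor bringing 2012–2017 BRL to Mar/2023 prices
DEFAULT_INFLATION_FACTOR = 1.5769934
#: BRL→USD exchange rate of March 31, 2023
DEFAULT_BRL_TO_USD = 0.1968581

INPATIENT_COST_CATEGORIES = frozenset(
    {ClaimCategory.INPATIENT_ADMISSION, ClaimCategory.SURGERY}
)
OUTPATIENT_COST_CATEGORIES = frozenset(
    {ClaimCategory.OUTPATIENT_VISIT, ClaimCategory.PROCEDURE, ClaimCategory.ER_VISIT}
)


@dataclass(slots=True)
class MonthConvention:
    days_per_month: float = DAYS_PER_MONTH

    def __post_init__(self) -> None:
        if self.days_per_month <= 0:
            raise ValueError("days_per_month must be positive")


@dataclass(slots=True)
class DurationSummary:
    n: int
    mean: float
    sd: float
    median: float
    iqi_low: float
    iqi_high: float


@dataclass(slots=True)
class PPPMEstimate:
    point: float
    ci_low: float
    ci_high: float
    family: str  # "poisson" | "gamma"
    n_patients: int
    total_exposure_months: float


@dataclass(slots=True)
class CurrencyParameters:
    inflation_factor: float = DEFAULT_INFLATION_FACTOR
    brl_to_usd: float = DEFAULT_BRL_TO_USD

    def __post_init__(self) -> None:
        if self.inflation_factor <= 0 or self.brl_to_usd <= 0:
            raise ValueError("currency parameters must be strictly positive")


@dataclass(slots=True)
class CostBreakdown:
    """Treatment-period cost totals; medication costs are excluded by design."""

    inpatient_brl: float
    outpatient_brl: float
    total_brl: float
    inpatient_usd: float
    outpatient_usd: float
    total_usd: float
    medication_excluded: bool = True


def months_between(d1: date, d2: date, conv: MonthConvention | None = None) -> float:
    """Calendar-day difference divided by the month length; d1 must precede d2."""
    if d1 > d2:
        raise ValueError(f"dates out of order: {d1} > {d2}")
    conv = conv or MonthConvention()
    return (d2 - d1).days / conv.days_per_month


def treatment_duration(line: LineOfTherapy, conv: MonthConvention | None = None) -> float:
    """Months from a line's first to last claim (0 for a single-claim line)."""
    return months_between(line.start_date, line.end_date, conv)


def ttnt(
    line_n: LineOfTherapy,
    line_next: LineOfTherapy,
    conv: MonthConvention | None = None,
) -> float:
    """Time to next treatment: months between consecutive line initiations."""
    if line_next.start_date <= line_n.start_date:
        raise ValueError("next line must start strictly after the current line")
    return months_between(line_n.start_date, line_next.start_date, conv)


def summarize(values: list[float] | np.ndarray) -> DurationSummary:
    """Mean, sample SD (n−1), median and interquartile interval.

    Quantiles use linear interpolation between order statistics.  A single
    value reports SD 0 by convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return DurationSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(q50),
        iqi_low=float(q25),
        iqi_high=float(q75),
    )


def restrict_to_treatment_periods(
    claims: list[ClaimRecord],
    lines: list[LineOfTherapy],
    conv: MonthConvention | None = None,
    exposure_floor: float = EXPOSURE_FLOOR_MONTHS,
) -> tuple[list[ClaimRecord], float]:
    """Keep only claims dated inside a line of therapy and compute exposure.

    Intervals are closed on both ends, so claims on a line boundary are
    kept.  Exposure is the sum of per-line durations in months, each floored
    at ``exposure_floor`` so a single-day line still contributes exposure.
    Periods between lines represent care unrelated to active treatment and
    are dropped.
    """
    conv = conv or MonthConvention()
    intervals = [(ln.start_date, ln.end_date) for ln in lines]
    kept = [
        c for c in claims if any(lo <= c.service_date <= hi for lo, hi in intervals)
    ]
    exposure = sum(
        max(months_between(lo, hi, conv), exposure_floor) for lo, hi in intervals
    )
    return kept, exposure


def poisson_exact_ci(count: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) chi-square confidence bounds for a Poisson count."""
    alpha = 1.0 - conf
    lo = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2)
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * (count + 1)) / 2)
    return lo, hi


def pppm_count(
    total_events: int, exposure_months: float, n_patients: int
) -> PPPMEstimate:
    """Pooled event rate per patient-month with an exact Poisson 95% CI.

    The interval is the Garwood bound on the total count divided by the
    exposure — appropriate for the small subgroup counts that occur in
    stratified utilization tables.
    """
    if exposure_months <= 0:
        raise ValueError("exposure must be positive")
    if total_events < 0:
        raise ValueError("event count must be non-negative")
    lo, hi = poisson_exact_ci(total_events)
    return PPPMEstimate(
        point=total_events / exposure_months,
        ci_low=lo / exposure_months,
        ci_high=hi / exposure_months,
        family="poisson",
        n_patients=n_patients,
        total_exposure_months=exposure_months,
    )


def pppm_count_per_patient_mean(
    events_by_patient: list[int], exposure_by_patient: list[float]
) -> float:
    """Alternative PPPM point estimate: mean of per-patient rates."""
    rates = [e / x for e, x in zip(events_by_patient, exposure_by_patient) if x > 0]
    if not rates:
        raise ValueError("no patients with positive exposure")
    return float(np.mean(rates))


def pppm_cost(
    per_patient_pppm: list[float] | np.ndarray,
    total_exposure_months: float | None = None,
) -> PPPMEstimate:
    """Mean per-patient PPPM cost with a moment-matched gamma 95% CI.

    A gamma with shape k = m²/v and scale θ = v/m is matched to the
    per-patient values (m, v their mean and sample variance); the CI is the
    2.5%/97.5% quantile pair of the distribution of the mean of n such
    gammas, i.e. gamma(n·k, θ/n).  Healthcare costs are non-negative and
    right-skewed, which this family captures where a normal interval would
    dip below zero.
    """
    arr = np.asarray(per_patient_pppm, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one patient")
    if np.any(arr < 0):
        raise ValueError("costs must be non-negative")
    n = arr.size
    m = float(arr.mean())
    exposure = float(total_exposure_months) if total_exposure_months is not None else float("nan")
    if m == 0:
        return PPPMEstimate(0.0, 0.0, 0.0, "gamma", n, exposure)
    v = float(arr.var(ddof=1)) if n > 1 else 0.0
    if v == 0:
        return PPPMEstimate(m, m, m, "gamma", n, exposure)
    shape = m * m / v
    scale = v / m
    lo = float(stats.gamma.ppf(0.025, a=n * shape, scale=scale / n))
    hi = float(stats.gamma.ppf(0.975, a=n * shape, scale=scale / n))
    return PPPMEstimate(m, lo, hi, "gamma", n, exposure)


def adjust_and_convert(
    nominal_brl: float,
    params: CurrencyParameters | None = None,
    already_adjusted: bool = False,
) -> tuple[float, float]:
    """Inflation-adjust a nominal BRL amount and convert to USD.

    Returns (adjusted BRL, USD).  With ``already_adjusted`` the inflation
    step is skipped and only the exchange rate applies.
    """
    if nominal_brl < 0:
        raise ValueError("amounts must be non-negative")
    params = params or CurrencyParameters()
    adjusted = nominal_brl if already_adjusted else nominal_brl * params.inflation_factor
    return adjusted, adjusted * params.brl_to_usd


def aggregate_costs(
    claims: list[ClaimRecord],
    params: CurrencyParameters | None = None,
) -> CostBreakdown:
    """Treatment-period cost totals by care setting, in adjusted BRL and USD.

    Inpatient = admissions + breast surgery; outpatient = office visits,
    procedures and ER visits.  Drug-claim costs are excluded entirely (the
    source data cannot attribute medication costs to a setting), as are
    diagnosis and radiotherapy claims, so total = inpatient + outpatient
    exactly.
    """
    params = params or CurrencyParameters()
    inpat_nominal = sum(
        c.cost_brl_nominal for c in claims if c.category in INPATIENT_COST_CATEGORIES
    )
    outpat_nominal = sum(
        c.cost_brl_nominal for c in claims if c.category in OUTPATIENT_COST_CATEGORIES
    )
    inpat_brl, inpat_usd = adjust_and_convert(inpat_nominal, params)
    outpat_brl, outpat_usd = adjust_and_convert(outpat_nominal, params)
    return CostBreakdown(
        inpatient_brl=inpat_brl,
        outpatient_brl=outpat_brl,
        total_brl=inpat_brl + outpat_brl,
        inpatient_usd=inpat_usd,
        outpatient_usd=outpat_usd,
        total_usd=inpat_usd + outpat_usd,
    )
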