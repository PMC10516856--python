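# Methods

`tnbc_claims` implements a claims-database analysis pipeline for
triple-negative breast cancer (TNBC): cohort selection from longitudinal
administrative claims, claims-based inference of disease stage, line-of-
therapy (LOT) construction, treatment-setting classification, and
per-patient-per-month (PPPM) utilization and cost estimation. Because real
oncology claims databases are proprietary, the package ships a synthetic
claims generator with exported ground truth; every algorithm is validated
by recovery against that truth and by independent oracles.

## Cohort selection

A patient is eligible when all of the following hold:

* age ≥ 18 at the first claim (patients with missing age are retained and
  flagged, mirroring incomplete demographic capture in claims exports);
* ≥ 1 diagnosis claim with ICD-10 category C50 (any fourth character)
  inside the study window, 2012-01-01 to 2017-12-31;
* ≥ 1 drug claim for an inclusion-list molecule (cytotoxic chemotherapy
  used for TNBC);
* no drug claim, ever, for an exclusion-list molecule (hormone therapy or
  HER2-targeted therapy — their presence implies the tumour is not
  triple-negative);
* no breast-cancer activity in the 2011 washout year, operationalised as
  any C50 diagnosis claim or any inclusion/exclusion-molecule drug claim
  dated in 2011. The washout exists to exclude prevalent cases; whether
  "any BC treatment" should also cover procedures is ambiguous, and we
  deliberately restrict it to drug claims because the molecule lists are
  the only operational definition of breast-cancer treatment the design
  provides. This choice is configurable only by editing the rule, and is
  flagged here.

The index date is the date of the first C50 claim in the window. Rules are
evaluated independently and all failures are reported, so eligibility is
invariant to claim order.

The default inclusion list (doxorubicin, cyclophosphamide, paclitaxel,
docetaxel, carboplatin, cisplatin, gemcitabine, capecitabine, fluorouracil,
bevacizumab) and exclusion list (tamoxifen, anastrozole, letrozole,
exemestane, fulvestrant, trastuzumab, pertuzumab, lapatinib) are assembled
from the agents such cohorts actually receive; the full vocabularies used
by any particular payer are configurable through the catalog file, and the
defaults are documented approximations, not a canonical standard.

## Staging

Claims carry no AJCC stage. Stage IV (metastatic) disease is inferred when
at least two *qualifying claims* occur **≥ 15 days apart** inside a staging
window around the index date. Qualifying claims are (a) diagnosis claims
whose ICD-10 category is C76–C80, excluding subcode C77.3 (axillary /
upper-limb node secondaries: regional rather than distant spread), in
either dotted or undotted dialect, and (b) claims bearing a configured
metastatic-management procedure code. Decisions worth stating explicitly:

* window bounds: "one month before" = 30 days, "six months after" = 183
  days (6 × 30.4375, rounded), both endpoints inclusive — consistent with
  the 30.4375-day month used everywhere else;
* the two claims may mix categories (one metastatic ICD code plus one
  management procedure qualifies), treating the evidence as a pooled set;
* the same code on two sufficiently separated dates qualifies — distinct
  codes are not required;
* separation is a strict calendar-day difference ≥ 15.

These semantics are pinned by a brute-force oracle test that enumerates
all pairs of qualifying claims. Adding evidence is monotone: it can flip a
patient early → metastatic, never the reverse.

## Lines of therapy

Drug claims for inclusion molecules are grouped into lines claim-by-claim
in date order:

* **gap rule** — a drug claim ≥ 120 days after the previous drug claim
  opens a new line, regardless of molecule;
* **switch rule** — a claim for a molecule not in the current regimen,
  dated ≥ 60 days after the current line's start, opens a new line.

The gap rule is checked first when both could fire. Molecules first seen
within 28 days of the line start (configurable) form the initial regimen;
a new molecule between day 28 and day 60 extends the regimen (a
modification, not a switch — the 60-day threshold exists precisely to keep
early additions from being misread as switches). The 60-day clock is
anchored at the line start, the common convention for claims LOT
algorithms. Each line's end date is its last constituent claim.

For early-stage patients in the surgery subcohort, regimens starting
strictly before the surgery date form the neoadjuvant (NAT) block and
those on/after it the adjuvant (AT) block, giving the NAT-only / AT-only /
NAT+AT setting split. Follow-on regimens are tagged *sequential* when the
gap from the previous regimen's end is ≤ 45 days (a planned continuation,
e.g. AC followed by a taxane) and *progressive disease* otherwise; the
45-day clock runs from the previous regimen's last claim, reading the
"45-day window" as bounding the treatment-free interval. Rule precedence
is: gap-120 → switch-60 when building lines, then sequential/progression
tagging on the resulting regimens. An exhaustive oracle test over day
offsets bracketing 45/60/120 pins all of this.

Metastatic patients' lines are numbered LOT1, LOT2, …; pre-surgery
chemotherapy for metastatic surgery patients is counted as neoadjuvant for
the NAT-share statistic while still occupying its slot in LOT numbering.

## PPPM metrics

* **Month convention**: 30.4375 days (365.25/12) for every day → month
  conversion.
* **Exposure restriction**: only claims dated inside a line (closed
  intervals) count, and exposure is the summed line durations in months —
  periods between treatments are excluded so utilization unrelated to
  active management is not attributed to it. Each line's exposure is
  floored at 0.25 month so single-visit lines do not produce zero
  denominators; the floor is configurable.
* **Event rates**: pooled (total events / total patient-months) with an
  exact Poisson (Garwood) 95% CI — chi-square quantiles on the total
  count, divided by exposure. Exact rather than normal intervals because
  stratified tables produce small counts. A mean-of-per-patient-rates
  variant is provided (`pppm_count_per_patient_mean`) since either reading
  of "mean events per patient during a month" is defensible; the pooled
  form is the default because it makes the Poisson interval well defined.
* **Costs**: per-patient PPPM values (patient's treatment-period costs /
  patient's exposure), summarised by their mean with a moment-matched
  gamma CI: fit shape k = m²/v, scale θ = v/m to the values, then take the
  2.5%/97.5% quantiles of the mean of n such gammas, i.e. gamma(n·k, θ/n).
  Healthcare costs are non-negative and right-skewed, which this family
  respects where a normal interval would go negative. The construction is
  pinned by simulation coverage tests (~95% over 200 replicates), not by
  an external reference.
* **Cost components**: inpatient = admissions + breast surgery;
  outpatient = office visits + procedures + ER visits; medication costs
  are excluded entirely (claims data cannot attribute them to a setting),
  as are diagnosis and radiotherapy claims, so total = inpatient +
  outpatient holds exactly at every aggregation level.
* **Currency**: one average inflation factor (1.5769934) brings nominal
  2012–2017 BRL to Mar/2023 prices, then a fixed rate (0.1968581 BRL→USD)
  converts; the chain is linear, and per-year deflators are deliberately
  out of scope.
* **Summaries**: sample SD with n−1 (0 by convention for a single value);
  quartiles by linear interpolation between order statistics; report
  tables round half-up — 2 decimals for currency and rates, 1 for
  percentages.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with defaults
set to the study conditions: 82.8% early-stage mix; surgery in 41.6%
(early) / 37.4% (metastatic); AT-only/NAT-only/NAT+AT split 75.3/7.5/17.1
among early surgery patients; sequential follow-on in 57.3% (AT) / 13%
(NAT+AT); 4.4% early progression; LOT2 after LOT1 with probability 0.484
and LOT3 after LOT2 with 0.126; 21-day cycles, 3–6 cycles per regimen;
PPPM event rates per stage (early: 0.23 admissions, 0.25 ER, 0.37 visits,
23.15 procedures; metastatic: 0.38/0.60/0.66/34.60); per-claim gamma costs
moment-matched so cohort-level PPPM costs land at realistic magnitudes
(≈37k adjusted BRL early, ≈51k metastatic). Regimen menus per stage/line
weight bevacizumab+paclitaxel at 21.6% of metastatic first-line therapy,
anthracycline-based neoadjuvant treatment, and taxane/gemcitabine/
capecitabine salvage lines.

Key design choices:

* Every simulated metastatic patient receives at least one systemic line:
  a patient with no inclusion-molecule claim could never enter the cohort,
  so a "no-LOT1" fraction would only create contaminants of a kind the
  selection rules already cover.
* Event counts are drawn per line as Poisson(rate × line-months) — by
  Poisson additivity identical in law to month-by-month draws — with event
  days uniform in the line interval. Because the metrics engine measures
  exposure over exactly the same intervals, rate recovery is exact in
  expectation, which is what makes the parameter-recovery tests sharp.
* Planned follow-on regimens are laid out so the LOT rules recover them
  exactly: a molecule-disjoint regimen after an 18–60-day gap (recovered
  via the switch rule; 3+ cycles of 21 days guarantee the 60-day clock has
  expired), or any regimen after a 120+-day gap. A planned "sequential"
  regimen therefore always starts ≥ 60 days after the previous line start
  — a deliberate constraint, since a new molecule before day 60 would be
  absorbed into the current regimen and the planted truth would be wrong.
* A NAT-only patient who draws a progression regimen becomes NAT+AT in
  truth, because the progression regimen necessarily starts after surgery.
* A NAT+AT patient without a planned sequential follow-on has an adjuvant
  regimen starting more than 45 days after the neoadjuvant regimen ends,
  so the 45-day rule tags that regimen "progressive disease". This is a
  property of the rule (it does not see the surgery), not a generator
  defect; the exported truth records the tag the rule produces.
* Contaminants each violate exactly one rule: screening-only patients
  (C50 claim, no chemotherapy), hormone-therapy users (one tamoxifen
  claim added to an otherwise valid history), and pre-2012-activity
  patients (a 2011 C50 claim added). This makes per-reason rejection
  counts exactly testable.
* One global seed spawns a named substream per patient
  (`SeedSequence(seed, index)`), so growing the cohort never perturbs
  existing patients' draws.

What the generator does **not** emulate: real billing-code taxonomies and
package codes (a documented source of surgery/radiotherapy under-capture
in real data), death and censoring, geographic or temporal correlation,
dose/units, and misclassification noise (metastatic evidence is planted
only for true metastatic patients). Passing recovery tests therefore show
algorithmic correctness under the stated assumptions — not robustness to
the coding noise of a particular payer's export.

## Problem sizes used in tests

Unit and property suites run on fixtures and 300–600-patient cohorts; the
acceptance suite uses one 3000-patient cohort (the scale at which the
binomial ±2-point bound on the stage mix is meaningful), 200-replicate
coverage runs for both interval families, and exhaustive LOT/staging
oracle enumerations (tens of thousands of tiny cases). The whole suite
completes in well under a minute.

## Known limitations

* The inclusion/exclusion molecule lists and metastatic-management code
  set are configurable approximations; results on real data depend on the
  payer-specific vocabularies supplied.
* The 60-day switch clock anchored at line start, the 28-day grouping
  window, and the treatment of sub-60-day molecule additions as regimen
  modifications are conventions — defensible, test-pinned, and
  configurable, but not uniquely determined by the rule statements.
* PPPM cost CIs assume per-patient PPPM values are approximately gamma;
  heavy contamination (many zero-cost patients) degrades the moment match
  (the all-zero case degenerates to a point interval by convention).
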