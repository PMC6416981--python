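# Methods

## Problem and scope

`cqmbench` measures the *clinical realism* of a synthetic EHR population
by computing four widely reported clinical quality measures over the
five-table Synthea CSV dialect (patients, encounters, conditions,
observations, procedures) and comparing the resulting rates — with
percentile-bootstrap confidence intervals — against publicly reported
Massachusetts and national rates. It also ships a synthetic cohort
generator with *configurable post-service outcome probabilities*, so the
whole pipeline can be exercised, calibrated and property-tested without
a multi-gigabyte download. The generator is a parameterized statistical
stand-in, not a state-machine patient simulator: it reproduces the
statistical structure the measures inspect, nothing more.

## Measure logic

All dates are calendar dates; every interval is inclusive on both ends;
ages use the completed-years anniversary rule anchored at the
measurement-period end. The period defaults are calendar 2016 for the
three outcome measures and 2015-01-01..2016-12-31 for screening
(eligibility requires being alive through both years; lookbacks anchor
at 2016-12-31).

**Colorectal Cancer Screening** (per patient). Denominator: age 50–75 at
period end, alive through the period ("alive" = no death date, or death
on/after the period end; an `alive_any_point` flag selects the laxer
reading). Numerator: any procedure matching one of five modality value
sets within its lookback ending at the period end — colonoscopy 10 y,
flexible sigmoidoscopy 5 y, CT colonography 5 y, FOBT 1 y, stool DNA
3 y. The lookback is anchored at the period end, not at each patient's
last visit: the source specifications are anchor-ambiguous and a fixed
anchor is the only deterministic choice.

**COPD 30-Day Mortality** (per *encounter*). Strict denominator:
in-period encounters whose principal diagnosis is in the COPD value set
({185086009, 84733001} — the only two COPD codes the synthetic source
uses). Expanded denominator: additionally any in-period encounter whose
patient has a COPD condition active (inclusive bounds) at the encounter
start. Numerator: patient death within [start, start + 30 d], regardless
of discharge date. A patient with several index admissions contributes
each of them.

**Complications after Hip/Knee Replacement** (per patient). Index = first
in-period procedure coded 609588000 (total knee) or 52734007 (total
hip). Numerator: any of ten rules — heart attack, pneumonia, sepsis,
septicemia/shock within 7 d; surgical-site bleeding, pulmonary embolism,
death within 30 d; mechanical complication, periprosthetic joint
infection, wound infection within 90 d. Non-death rules match either a
condition onset or an encounter principal diagnosis (the permissive
reading); risk adjustment and the official exclusion logic are out of
scope — these are raw rates.

**Controlling High Blood Pressure** (per patient). Denominator: age
18–85 at period end with a hypertension condition (38341003) active at
any point of the period. Numerator: the most recent paired
systolic/diastolic reading (LOINC 8480-6/8462-4, paired by shared date)
dated on/after the earliest hypertension onset and inside the period is
strictly below 140/90 mmHg (age 18–59, or 60–85 with active diabetes)
or 150/90 mmHg (60–85 without diabetes). "Most recent" follows the
HEDIS convention; an `all_readings` flag demands every qualifying
reading be controlled. Ties on the same date resolve toward the highest
(systolic, diastolic) pair — the conservative choice. Unpaired readings
are counted in the result notes and ignored. The shipped diabetes value
set is a placeholder (`SYN-DIABETES`) that real-data users must replace.

## Value sets

Codes printed in the source measure descriptions ship as real SNOMED-CT
defaults; value sets whose official contents are not redistributable
(the five screening modalities, seven of the complication sets,
diabetes) ship as clearly marked `SYN-*` placeholder codes rather than
guessed clinical codes. The generator emits the same placeholders, so
engine and generator agree end-to-end; for real Synthea data the
config file `valuesets.yaml` must be replaced with official VSAC sets.
ICD-10/CPT codes translate through a one-to-many code map; unmapped
codes are reported, never fatal.

## Bootstrap

Confidence intervals are percentile bootstrap over the denominator
units' boolean compliance vector (1000 resamples, alpha 0.05 by
default). For a binary vector, resampling n flags with replacement makes
the resample numerator exactly Binomial(n, k/n); the implementation
draws from that distribution directly, which is distribution-identical
to explicit resampling and O(resamples) instead of O(n·resamples).
Constant vectors return a degenerate point interval; an empty
denominator returns no interval. The resampling unit is the measure's
denominator unit (encounters for COPD, patients otherwise).

## Synthetic cohort generator

One two-year horizon (2015–2016) is simulated; event-level activity
(index admissions, surgeries, BP readings) is placed in the final
calendar year, screening procedures inside each modality's lookback.
Defaults encode the published demographic marginals of the SyntheticMass
population: age bands 19.2/64.5/16.3 % (<18 / 18–64 / ≥65, uniform ages
within band, 65–95 for the open band), 51 % female, height normal and
weight log-normal per sex calibrated to the published means (male
97.98 kg / 176.77 cm, female 86.04 kg / 163.33 cm; calibration is
mean-level only — the full BMI category distribution of the source is
not reproducible from an independent height/weight model and is not
asserted). Adult hypertension prevalence defaults to 0.30.

Outcome channels are constructed to make parameter recovery exact in
expectation:

* COPD index admissions are Poisson per COPD patient, spaced ≥ 31 days
  apart and truncated at death, so each emitted admission is an
  independent Bernoulli(`copd_mortality_30d`) trial with no
  cross-window contamination.
* Complications materialize as a condition row plus a follow-up
  encounter at index + U{0..window} days, per rule, with the configured
  probability.
* Every hypertensive patient receives at least one paired BP reading in
  the event year, on distinct days (sampled without replacement), and
  only the last reading's control status is the configured Bernoulli —
  so the engine rate recovers `bp_control_prob` exactly. Controlled
  readings are drawn below 140/90 and uncontrolled ones at/above
  150/90, so control status is invariant to which threshold rule
  applies.
* Screening offers go to patients the engine will deem eligible, with a
  date uniform inside the chosen modality's lookback, so the screening
  rate recovers `screening_offer_prob`.

Two generator fields beyond the obvious ones: `visit_rate` adds
background ambulatory encounters (needed for the expanded COPD
denominator to be a strict superset of strict mode), and
`diabetes_prev_adult` exercises the BP threshold split. A final cleanup
drops any event dated after a patient's death, preserving referential
and temporal integrity; with mixed outcome channels this can interact
(e.g. a death removing later readings), which is why recovery tests
isolate one channel at a time.

`paper_mimic_config()` bundles the degenerate regime the package is
built to reproduce: screening offered at 0.687 with only colonoscopy
and FOBT in the mix (0.9/0.1), sparse principal-diagnosis COPD
admissions (prevalence 0.055, 0.0077 admissions/patient/yr ≈ the
published per-capita admission volume), 30-day mortality 0.007, joint
replacements at 4×10⁻⁴ of patients 45+, hypertension prevalence 0.2991,
and *all* complication and BP-control probabilities zero. Outcome
measures then return exactly-zero numerators over non-empty
denominators while the screening rate stays realistic — the
qualitative signature of guideline-driven synthetic data that models
service delivery but not post-service outcomes.

What the generator does **not** emulate: geography and census seeding,
care heterogeneity across providers, background (non-COPD) mortality,
comorbidity correlation structure, longitudinal BP trajectories, cost
fields. Passing tests therefore demonstrate correctness of the measure
logic and calibration machinery, not realism of any particular clinical
claim on real data.

## Numerical and testing choices

Problem sizes: property tests use cohorts of 200–80,000 patients chosen
so binomial 3σ recovery bands are informative (denominators ≥ 5,000 for
recovery checks; the paper-mimic regime is checked at n = 50,000 where
the screening denominator is ≈ 13,000). The measure engine is verified
against an independent brute-force enumerator (pure-Python loops over
rows) on 50 random small cohorts; the bootstrap against the closed-form
normal-approximation binomial interval. CSV round-trips are exact:
floats serialize via shortest round-trip `repr` and parse via `float`.
Fixed seeds yield byte-identical CSVs and bit-identical intervals.

Known limitations: raw (unadjusted) rates only; no measure exclusions
(hospice, colectomy, ESRD…); single-period simulation with no
life-course history; placeholder value sets require substitution before
any real-data use; the expanded-COPD published figures are internally
inconsistent in the source reporting, so no quantitative target is
asserted for that mode.
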