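# cqmbench

Clinical quality measures over Synthea-style EHR tables — a toolkit for
validating synthetic patient populations from the healthcare-quality
perspective.

Synthetic EHR generators such as Synthea model care processes after
clinical guidelines. A natural way to probe their realism is to compute
the same electronic clinical quality measures (eCQMs) that are publicly
reported for real populations and compare the rates. `cqmbench`
implements four such measures over the five-table Synthea CSV export
dialect (patients, encounters, conditions, observations, procedures):

| Measure | Type | Unit | Logic sketch |
|---|---|---|---|
| Colorectal Cancer Screening | process | patient | age 50–75, any of 5 modalities within its lookback (10/5/5/1/3 y) |
| COPD 30-Day Mortality | outcome | encounter | principal-dx COPD admission (strict) or COPD-active encounter (expanded); death ≤ 30 d |
| Complications after Hip/Knee Replacement | outcome | patient | index knee/hip arthroplasty (SNOMED 609588000 / 52734007); 10 complication rules in 7/30/90-d windows |
| Controlling High Blood Pressure | outcome | patient | hypertension (38341003) active; latest BP pair < 140/90 or 150/90 mmHg by age/diabetes |

Each measure returns denominator and numerator counts, the rate
p = numerator/denominator, and a 95 % percentile-bootstrap confidence
interval (1000 resamples over the denominator units). A reporting layer
compares the rates against publicly reported Massachusetts and national
reference rates, and a synthetic cohort generator with *configurable
outcome probabilities* makes every stage testable — including the
degenerate regime where services are delivered at realistic rates but
no post-service outcome ever occurs.

## Worked example

```python
from cqmbench import (MeasureConfig, compare_rates, generate,
                      load_reference_rates, paper_mimic_config, run_all)

cohort = generate(paper_mimic_config(n_patients=50_000, seed=1))
results = run_all(cohort, MeasureConfig())
for r in results:
    rate = "NA" if r.rate is None else f"{100 * r.rate:.1f}%"
    print(f"{r.measure_name}: {rate} ({r.numerator}/{r.denominator})")
```

prints

```
colorectal_screening: 68.6% (9146/13326)
copd_mortality: 0.0% (0/16)
hip_knee_complications: 0.0% (0/11)
bp_control: 0.0% (0/11403)
```

Read: of 13,326 patients aged 50–75 alive through 2015–2016, 68.6 %
had a qualifying screening — the configured service-delivery
probability (0.687) is recovered. The three outcome measures have
non-empty denominators (16 COPD admissions, 11 joint replacements,
11,403 hypertensive adults) but zero numerators, because the
paper-mimic configuration sets every post-service outcome probability
to zero: the signature of synthetic data that models services being
offered but not what happens afterwards. `compare_rates(results,
load_reference_rates())` then reports the gaps against the real-world
Massachusetts rates (77.3 %, 7.0 %, 2.9 %, 74.5 %).

The same pipeline is available from a shell:

```sh
cqm-bench generate --out-dir cohort/ --seed 1 --n 50000
cqm-bench compute  --cohort-dir cohort/ --out-dir results/ [--copd-mode expanded]
cqm-bench report   --cohort-dir cohort/ --measures results/measures.json --out-dir results/
cqm-bench validate --seed 1          # generate → compute → check the expected pattern
```

To analyze a real Synthea export instead, point `--cohort-dir` at its
CSV directory and supply official VSAC value sets via
`MeasureConfig(valuesets_path=...)` — the shipped `valuesets.yaml`
contains the published SNOMED-CT codes plus clearly marked `SYN-*`
placeholders for sets whose official contents are not bundled.

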