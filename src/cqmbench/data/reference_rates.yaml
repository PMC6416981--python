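# Publicly reported real-world rates used as comparison references.
# Massachusetts rates: Hospital Compare (outcome measures) or aggregated
# Star Ratings of nine MA health plans (process/HEDIS measures).
# National rates: Hospital Compare or the 2017 HEDIS Medicare PPO report.
measures:
  colorectal_screening:
    massachusetts: 0.773
    national: 0.698
    source: "Star Ratings (MA plans) / HEDIS 2017 Medicare PPO"
  copd_mortality:
    massachusetts: 0.070
    national: 0.080
    source: "Hospital Compare (MA: 1233/17636, range 5.2-9.3%)"
  hip_knee_complications:
    massachusetts: 0.029
    national: 0.028
    source: "Hospital Compare (MA: 700/23949, range 1.9-4.4%)"
  bp_control:
    massachusetts: 0.7452
    national: 0.697
    source: "Star Ratings (MA plans) / HEDIS 2017 Medicare PPO"
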