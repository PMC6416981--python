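# Default value sets and cross-terminology code map.
#
# Numeric codes are real SNOMED-CT concepts; codes prefixed "SYN-" are
# synthetic placeholders for value sets whose official (VSAC) contents are
# not bundled.  The synthetic cohort generator emits the same placeholder
# codes, so the pipeline is fully exercisable end-to-end; for real-data
# replication replace the placeholder sets with the official VSAC sets.
valuesets:
  # colorectal-cancer screening modalities
  - {name: colonoscopy, system: other, codes: ["SYN-COLONOSCOPY"]}
  - {name: flexible_sigmoidoscopy, system: other, codes: ["SYN-FLEX-SIG"]}
  - {name: ct_colonography, system: other, codes: ["SYN-CT-COLONOGRAPHY"]}
  - {name: fobt, system: other, codes: ["SYN-FOBT"]}
  - {name: stool_dna, system: other, codes: ["SYN-STOOL-DNA"]}
  # joint-replacement index procedures
  - {name: total_knee_replacement, system: SNOMED-CT, codes: ["609588000"]}
  - {name: total_hip_replacement, system: SNOMED-CT, codes: ["52734007"]}
  # chronic conditions
  - {name: hypertension, system: SNOMED-CT, codes: ["38341003"]}
  - {name: copd, system: SNOMED-CT, codes: ["185086009", "84733001"]}
  - {name: diabetes, system: other, codes: ["SYN-DIABETES"]}
  # post-operative complications
  - {name: heart_attack, system: SNOMED-CT, codes: ["22298006"]}
  - {name: pneumonia, system: SNOMED-CT, codes: ["233604007"]}
  - {name: sepsis, system: other, codes: ["SYN-SEPSIS"]}
  - {name: septicemia_shock, system: other, codes: ["SYN-SEPTICEMIA-SHOCK"]}
  - {name: surgical_site_bleeding, system: other, codes: ["SYN-SURGICAL-SITE-BLEEDING"]}
  - {name: pulmonary_embolism, system: other, codes: ["SYN-PULMONARY-EMBOLISM"]}
  - {name: mechanical_complication, system: other, codes: ["SYN-MECHANICAL-COMPLICATION"]}
  - {name: periprosthetic_joint_infection, system: other, codes: ["SYN-PJI"]}
  - {name: wound_infection, system: other, codes: ["SYN-WOUND-INFECTION"]}
codemap:
  # small worked examples of ICD-10 -> SNOMED-CT translation
  - {from_system: ICD-10, from_code: I10, to_snomed: ["38341003"]}
  - {from_system: ICD-10, from_code: J43.9, to_snomed: ["84733001"]}
  - {from_system: ICD-10, from_code: J44.9, to_snomed: ["185086009"]}
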