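# Default reference-intake thresholds used by the analysis scripts.
# These are configuration inputs, not package constants: edit freely.
# EAR = Estimated Average Requirement (prevalence of inadequacy = % below);
# AI = Adequate Intake (adequacy = % at or above).
# Units follow the package registry: calcium/magnesium/potassium mg/d,
# vitamin_a RAE ug/d, vitamin_d ug/d.
dri:
  calcium:
    - {age_lo: 2, age_hi: 3, value: 500, kind: EAR}
    - {age_lo: 4, age_hi: 8, value: 800, kind: EAR}
    - {age_lo: 9, age_hi: 18, value: 1100, kind: EAR}
    - {age_lo: 19, age_hi: 50, value: 800, kind: EAR}
    - {sex: male, age_lo: 51, age_hi: 70, value: 800, kind: EAR}
    - {sex: female, age_lo: 51, age_hi: 70, value: 1000, kind: EAR}
    - {age_lo: 71, age_hi: 200, value: 1000, kind: EAR}
  magnesium:
    - {age_lo: 2, age_hi: 3, value: 65, kind: EAR}
    - {age_lo: 4, age_hi: 8, value: 110, kind: EAR}
    - {age_lo: 9, age_hi: 13, value: 200, kind: EAR}
    - {sex: male, age_lo: 14, age_hi: 18, value: 340, kind: EAR}
    - {sex: female, age_lo: 14, age_hi: 18, value: 300, kind: EAR}
    - {sex: male, age_lo: 19, age_hi: 30, value: 330, kind: EAR}
    - {sex: female, age_lo: 19, age_hi: 30, value: 255, kind: EAR}
    - {sex: male, age_lo: 31, age_hi: 200, value: 350, kind: EAR}
    - {sex: female, age_lo: 31, age_hi: 200, value: 265, kind: EAR}
  vitamin_a:
    - {age_lo: 2, age_hi: 3, value: 210, kind: EAR}
    - {age_lo: 4, age_hi: 8, value: 275, kind: EAR}
    - {age_lo: 9, age_hi: 13, value: 445, kind: EAR}
    - {sex: male, age_lo: 14, age_hi: 18, value: 630, kind: EAR}
    - {sex: female, age_lo: 14, age_hi: 18, value: 485, kind: EAR}
    - {sex: male, age_lo: 19, age_hi: 200, value: 625, kind: EAR}
    - {sex: female, age_lo: 19, age_hi: 200, value: 500, kind: EAR}
  vitamin_d:
    - {age_lo: 2, age_hi: 200, value: 10, kind: EAR}
  potassium:
    - {age_lo: 2, age_hi: 3, value: 3000, kind: AI}
    - {age_lo: 4, age_hi: 8, value: 3800, kind: AI}
    - {age_lo: 9, age_hi: 13, value: 4500, kind: AI}
    - {age_lo: 14, age_hi: 200, value: 4700, kind: AI}
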