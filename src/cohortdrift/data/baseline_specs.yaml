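# Baseline (Survey-1) risk-factor distributions for the synthetic cohort of
# Australian women born 1921-26, expressed over complete cases. References for
# ordinal factors are the end category associated with best survival; nominal
# factors default to the modal category.
factors:
  - name: country_of_birth
    scale: nominal
    reference: Australia
    categories:
      Australia: 0.771
      Other English speaking: 0.135
      Other: 0.094
  - name: highest_qualification
    scale: ordinal
    reference: University
    categories:
      University: 0.042
      Certificate/Diploma: 0.081
      Trade/Apprenticeship: 0.037
      Any high school: 0.522
      No formal qualification: 0.318
  - name: bmi_group
    scale: nominal
    reference: Acceptable
    categories:
      Acceptable: 0.502
      Overweight: 0.331
      Obese: 0.135
      Underweight: 0.032
  - name: physical_activity
    scale: ordinal
    reference: Low to very high
    categories:
      Low to very high: 0.724
      None or very low: 0.276
  - name: alcohol
    scale: ordinal
    reference: Low-risk drinker
    categories:
      Low-risk drinker: 0.342
      Non-drinker: 0.336
      Rarely drinks: 0.288
      Risky or high-risk drinker: 0.034
  - name: smoking
    scale: ordinal
    reference: Never smoker
    categories:
      Never smoker: 0.629
      Ex-smoker: 0.299
      Smoker: 0.072
  - name: self_reported_health
    scale: ordinal
    reference: Excellent
    categories:
      Excellent: 0.065
      Very good: 0.279
      Good: 0.393
      Fair: 0.225
      Poor: 0.038

# Per-variable item missingness imposed completely at random.
missingness:
  bmi_group: 0.110
  smoking: 0.074
  country_of_birth: 0.070

# Area strata: population shares and relative sampling fractions (rural and
# remote intentionally over-sampled roughly two-fold).
strata:
  population_shares:
    city: 0.70
    rural: 0.25
    remote: 0.05
  sampling_fractions:
    city: 1.0
    rural: 2.0
    remote: 2.0

# Survey-5 attrition-status marginals used to calibrate model intercepts.
survey5_marginals:
  respondent: 0.447
  dead: 0.284
  frail: 0.051
  withdrawn: 0.114
  lost: 0.104
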