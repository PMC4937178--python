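# Default cardiorespiratory-fitness classification bands.
#
# Bands map an estimated VO2max (mL/kg/min) to an ordered fitness category
# within an age x sex stratum.  These defaults are the package's own,
# deliberately round-numbered bands in the spirit of the standard ACSM-style
# percentile tables (whose exact values are copyright-bound and therefore not
# shipped); edit this file or point --classes at your own to use real norms.
#
# `cutoffs` are the upper bounds (exclusive) separating consecutive
# categories; values below the first cutoff fall in the lowest category,
# values at or above the last cutoff in the highest.
name: default-crf-bands
categories: [sedentary, poor, fair, good, excellent]
strata:
  - {sex: F, age_min: 1, age_max: 29, cutoffs: [31, 36, 40, 44]}
  - {sex: F, age_min: 30, age_max: 39, cutoffs: [29, 34, 38, 42]}
  - {sex: F, age_min: 40, age_max: 49, cutoffs: [28, 32, 36, 40]}
  - {sex: F, age_min: 50, age_max: 59, cutoffs: [25, 30, 34, 38]}
  - {sex: F, age_min: 60, age_max: 119, cutoffs: [23, 28, 32, 36]}
  - {sex: M, age_min: 1, age_max: 29, cutoffs: [36, 41, 45, 49]}
  - {sex: M, age_min: 30, age_max: 39, cutoffs: [34, 39, 43, 47]}
  - {sex: M, age_min: 40, age_max: 49, cutoffs: [33, 37, 41, 45]}
  - {sex: M, age_min: 50, age_max: 59, cutoffs: [30, 35, 39, 43]}
  - {sex: M, age_min: 60, age_max: 119, cutoffs: [28, 33, 37, 41]}
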