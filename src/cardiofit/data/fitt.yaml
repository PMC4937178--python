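# Default FITT (frequency, intensity, time, type) ranges per fitness category.
#
# intensity is a fraction of heart-rate reserve (Karvonen %HRR), duration_min
# in minutes per session, frequency in sessions per week.  Prescription takes
# the MINIMUM of each range independently.
#
# The lowest band's minima (0.30 HRR, 30 min, 3 sessions/week) are the
# documented anchor for the sedentary example prescription (target HR 120 bpm
# -> 10,800 mBeats/week); the remaining ranges are editable package defaults.
name: default-fitt
rows:
  sedentary: {intensity: [0.30, 0.45], duration_min: [30, 40], frequency: [3, 5]}
  poor:      {intensity: [0.40, 0.55], duration_min: [30, 45], frequency: [3, 5]}
  fair:      {intensity: [0.50, 0.65], duration_min: [35, 50], frequency: [3, 5]}
  good:      {intensity: [0.60, 0.75], duration_min: [40, 55], frequency: [4, 6]}
  excellent: {intensity: [0.65, 0.85], duration_min: [40, 60], frequency: [4, 6]}
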