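# cardiofit

Heart-rate-based exercise prescription and training-load tracking, as a
tested Python library with a `cardiofit` command line.

Step-count goals ("10,000 steps/day") are easy to follow but ignore exercise
*intensity*, which is what drives cardiorespiratory fitness (CRF). This
package implements the computational core of an intensity-based program for
healthy adults with low-to-moderate fitness, the kind of engine a coaching
app or an exercise-physiology study pipeline needs:

* **Exercise prescription.** Training intensity is a fraction of heart-rate
  reserve (HRR = HRmax − HRrest, with HRmax defaulting to 220 − age).
  The Karvonen formula converts it to a target heart rate:
  `target_HR = (HRmax − HRrest) · intensity + HRrest`.
  A participant is classified into a fitness band from estimated VO2max
  (editable YAML tables), the band maps to FITT ranges (frequency,
  intensity, time), and the minimum of each range is prescribed.
* **mBeats — beats in zone.** The training-load metric is the number of
  heart beats accumulated while HR sits inside a personal zone around the
  target (±10 bpm by default). The weekly target is
  `target_HR × session_minutes × sessions_per_week`; each day the remaining
  weekly mBeats are split evenly over the remaining training days, so rest
  days target 0, bonus beats on rest days count, and a strong day lowers the
  targets that follow.
* **Submaximal fitness tests.** The Ruffier–Dickson squat test
  (45 s of squats at 40 bends/min, 3 min recovery) yields the recovery index
  `RDI = ((P1 − 70) + 2·(P2 − P0)) / 10` — P0 the 15-s resting mean, P1 the
  peak in the first 15 s of recovery, P2 the mean over recovery seconds
  60–75; lower is fitter. The Ebbeling single-stage treadmill walk estimates
  VO2max from the steady-state HR of a 5%-incline stage:
  `VO2max = 15.1 + 21.8·speed − 0.327·HR − 0.263·speed·age + 0.00504·HR·age + 5.98·sex`
  (speed in mph, sex coded 0 female / 1 male).
* **Synthetic data.** First-order HR kinetics (exponential onset/recovery),
  Gaussian sensor noise, lognormal daily steps, and three-arm pre/post study
  cohorts — all pure functions of (parameters, seed) with ground truth.
* **Study statistics.** Split-plot (mixed) ANOVA with Greenhouse–Geisser /
  Huynh–Feldt sphericity corrections (GG when ε < 0.75, HF otherwise),
  Tukey HSD follow-up, and Pearson correlation.

## Worked example

A sedentary participant with target HR 120 bpm, 30-minute sessions, three
times a week, training Mon/Wed/Fri:

```python
from cardiofit import (ExercisePrescription, TrainingWeekState, HRSeries,
                       HRZone, adaptive_daily_target, record_day)
import numpy as np

rx = ExercisePrescription.from_components(0.30, target_hr=120, session_minutes=30,
                                          frequency_per_week=3)
rx.weekly_mbeats_target        # 10800.0

week = TrainingWeekState.start(rx.weekly_mbeats_target, ["T","R","T","R","T","R","R"])
adaptive_daily_target(week)    # 3600.0  (and 0 on rest days)

# an enthusiastic first day: ~58 min steady at 120 bpm = 7000 beats in zone
day1 = HRSeries(np.arange(3500.0), np.full(3500, 120.0))
week = record_day(week, 0, day1, HRZone(110, 130))
week = record_day(week, 1, HRSeries(np.empty(0), np.empty(0)), HRZone(110, 130))
adaptive_daily_target(week)    # 1900.0  (3800 left over 2 training days)
```

The same flow from the shell:

```
$ cardiofit track --hr day1.csv --plan week.yaml --state state.json \
      --zone-low 110 --zone-high 130
day_index: 0
day_target: 3600.0
achieved: 7000.0
percent_of_target: 194.444
$ cardiofit status --state state.json        # after recording the rest day
current_day_index: 2
weekly_target: 10800.0
achieved_total: 7000.0
weekly_percent: 64.815
today_target: 1900.0
remaining_training_days: 2
```

10,800 is the weekly beats-in-zone budget (120 bpm × 30 min × 3), 3600 the
even per-session split, and 1900 the adapted daily target once 7000 beats
were banked on day one. Other subcommands: `cardiofit prescribe` (profile →
classification → prescription as JSON), `cardiofit test squat|treadmill`
(HR traces → RDI / VO2max), `cardiofit simulate bout|squat|treadmill|cohort`
(synthetic sessions with `truth.json` sidecars), and `cardiofit analyze`
(mixed ANOVA on a tidy cohort CSV).

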