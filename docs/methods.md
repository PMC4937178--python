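# Methods

This note records the models, defaults, and numerical conventions behind
`cardiofit`, and what the synthetic generators do and do not emulate.

## Prescription

Maximal HR defaults to the age-predicted `220 − age` (a profile can carry a
measured maximum, which then takes precedence). Intensity is prescribed as a
fraction of heart-rate reserve and converted with the Karvonen formula
`target = (HRmax − HRrest)·f + HRrest`; the function is strictly increasing
in `f` and maps the open interval (0, 1) onto (HRrest, HRmax). Target HR is
kept as a real number internally; rounding to integer bpm (round-half-even)
happens only at the display layer, so derived products such as the weekly
mBeats target stay exact.

Fitness classification and the FITT mapping are table lookups. The shipped
YAML tables are the package's own round-numbered defaults in the spirit of
the standard percentile norms, whose exact values are copyright-bound and
deliberately not reproduced; both are editable and schema-validated (unknown
keys rejected). Two facts are fixed and regression-tested: the lowest band
is labelled `sedentary`, and its FITT minima are 0.30 HRR, 30 min,
3 sessions/week — the anchor that makes a 120-bpm target produce the
10,800-mBeats weekly budget. Prescription takes the minimum of each FITT
range independently. Which intensity fractions apply to the higher bands is
a configuration choice, not a fixed fact; the defaults step up smoothly to
0.65 HRR.

## mBeats accounting

Wearables report bpm samples rather than beat events, so beats are
integrated per sample: a sample at `hr` bpm followed by a step `dt` seconds
contributes `hr/60 · dt` beats when it lies inside the zone (left-Riemann;
the final sample gets the nominal step, 1 s at 1 Hz). Only in-zone samples
count — there is no partial credit above or below the zone. Samples outside
(25, 250) bpm are flagged implausible and excluded. Gaps longer than 5 s
contribute zero beats: missing data is never interpolated, which makes the
count conservative under dropout.

The zone is `[target − 10, target + 10]` bpm by default. The width is a
package default chosen as a practical compromise — narrow enough that the
count reflects time at prescription intensity, wide enough that ±2–3 bpm
sensor noise around the target does not drop samples — and is configurable
everywhere a zone is accepted.

Daily targets are recomputed once per day, at day start: remaining weekly
mBeats divided by the number of remaining training days (current day
included), clamped at zero once the week's budget is met. Rest days always
target 0, but beats collected on them count fully toward the week ("bonus"),
lowering later targets. If training days run out with budget outstanding,
the target is 0 and a warning is logged. A zero-target day reports 100%
progress when nothing was collected (its goal is trivially met).

## Fitness tests

All analysis windows are half-open `[a, b)` seconds. Squat test: P0 is the
mean over the final 15 s of rest — the placement closest to exercise onset,
chosen because the protocol only fixes the window length; P1 the maximum
over recovery `[0, 15)`; P2 the mean over recovery `[60, 75)`. Insufficient
coverage of any window raises an error naming the window. The recovery index
is computed as `((P1 − 70) + 2·(P2 − P0)) / 10`, the standard
Ruffier–Dickson form with the divisor applying to the whole sum.

Treadmill walk: minute-7 and minute-8 HRs are 60-s means (`[360, 420)` and
`[420, 480)`); instantaneous end-of-minute values are a possible alternative
the protocol does not pin down, and means are less noise-sensitive. The test
ends when they differ by ≤ 6 bpm (inclusive), otherwise a ninth minute is
required. The stage HR entering the VO2max regression is the mean of the
final minute of the incline stage — again a choice, since "the HR" of the
stage is otherwise underdetermined. Speeds are mph end-to-end; the CLI
accepts km/h only via an explicit `--speed-kmh` flag with an exact
conversion factor, to avoid silent unit bugs. The 50–75% of
age-predicted-maximum speed check uses closed bounds.

## Synthetic generators

HR dynamics are first-order: HR approaches the exercise target as
`target + (start − target)·e^(−t/τ_on)` and recovers toward rest with
`τ_rec`. This mono-exponential model is the simplest defensible response
shape for moderate steady loads; it ignores cardiovascular drift, the fast
(vagal) vs slow recovery phases, posture, temperature, and beat-to-beat
variability. `τ_on = 0` is allowed and means an instantaneous step to
target — the fast-kinetics limit, useful for exact closure checks.
Noise-free trajectories are clipped to `[HRrest, HRmax]` (the clip is
inactive for valid parameters). Measurement noise is additive i.i.d.
Gaussian bpm; ground truth is always computed on the noise-free trace.
`simulate_bout` returns the exercise bout itself by default; an exponential
recovery tail is appended only when `recovery_s > 0`, so in-zone ground
truth refers to the counted session unless the caller asks for the tail.

Personas map a scalar fitness level in [0, 1] onto physiology: resting HR
80 → 60 bpm, recovery τ 60 → 20 s, onset τ 45 → 20 s, squat-exercise target
`HRrest + (0.85 − 0.2·fitness)·reserve`, habitual steps 6000 → 11,000/day,
and true VO2max 20 → 45 mL/kg/min (spanning the low-fitness population the
tooling targets). Every component of the squat response — peak, resting HR,
recovery speed — improves monotonically with fitness, which is what makes
the recovery index fall monotonically with fitness in noiseless simulation
and correlate negatively with true VO2max under noise. Daily steps are
lognormal around the persona mean (free-living counts are right-skewed).

Cohort tables emulate a three-arm pre/post training study (a step-goal app
arm, an HR-zone app arm, a supervised gym arm): per subject,
`value = group baseline + random intercept + time effect (post only) +
residual`. Default baselines and per-arm time effects are set to the
magnitudes reported for such interventions (e.g. VO2max +0.95/+1.70/+1.85
mL/kg/min; SBP +1.19/−3.23/−5.75 mmHg); they are generator conditions for
power/calibration experiments, not quantities the package claims to
estimate. What passing tests on these cohorts shows is that the statistics
engine is calibrated (null rejection ≈ 5%) and recovers injected effects —
not that real interventions have these effect sizes. Random streams derive
from a single seed via named substreams, so adding a generator never
perturbs existing draws.

## Statistics

`mixed_anova` computes the classical split-plot decomposition with weighted
(cell-size) sums of squares; it requires every subject at every time level
but tolerates unequal group sizes. The group F uses the subjects-within-group
mean square; time and interaction use the within-subject error mean square.
With two within-subject levels sphericity holds trivially and no correction
is applied. With three or more, the Greenhouse–Geisser ε comes from the
pooled within-group covariance of the time levels
(`tr(CSC′)² / ((k−1)·tr((CSC′)²))` for an orthonormal contrast basis C), the
Huynh–Feldt ε from `(N(k−1)ε̂ − 2) / ((k−1)(N − g − (k−1)ε̂))` capped at 1,
and the conventional selection rule applies: GG when ε̂ < 0.75, HF
otherwise. Corrected p-values use the F distribution with ε-deflated dfs.
Degenerate inputs (zero error variance) are flagged; zero-effect sums of
squares report F = 0 rather than 0/0. Published mixed-design analyses
sometimes print within-subject dfs for three-group designs where (2, df)
would be expected; this engine always reports the textbook dfs.

Tukey HSD uses the studentized-range distribution (scipy) on subject-level
means (across-time means by default, or a single time level via `at_time`);
with two groups it reduces to the pooled two-sample t-test. Pearson
correlation is the standard product-moment form and refuses zero-variance
or n < 3 input. α = 0.05 is a reporting convention of the callers, never
enforced inside the engine.

## Problem sizes and tolerances

The verification suite runs at desk scale, chosen to make the checks sharp
without heavy computation: formula oracles at 1000 random inputs (1e-9
absolute agreement); simulator/counter closure over 100 seeds at 2-bpm noise
(mean absolute error under 2% of truth); ANOVA calibration over 1000 null
cohorts of 12 subjects per arm (rejection rate required in [0.03, 0.07]);
association sign recovery over 200 cohorts of 33 subjects. Exact identities
(the 10,800/3600/1900 worked example, noiseless test round trips, the RDI
linearity coefficients −0.2/+0.1/+0.2) are asserted exactly. The split-plot
engine is cross-checked against an independently coded sums-of-squares
oracle and against pingouin; the ε estimators against pingouin's to 1e-9.

## Known limitations

Beat counting from bpm samples is an approximation to true beat events;
at 1 Hz the discretization error is far below sensor noise. The kinetic
simulator produces smooth traces — estimator performance on real, artifact-
laden wearable data will be worse than the synthetic round trips suggest.
The classification/FITT defaults are placeholders to be replaced with
licensed norms for clinical use. The ANOVA engine covers the one-between ×
one-within layout only; no permutation or robust variants are provided.
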