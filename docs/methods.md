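# Methods

## The measurement problem

In a calibrated limit-of-stability (LoS) task a standing subject leans to
steer the centre of pressure (CoP) from a central home position to eight
peripheral targets and back, with the targets placed at 75 % of the subject's
own maximal CoP excursion in each cardinal direction.  The question the
toolkit answers is *where the CoP spends its time* during that task: a
postural-stability indicator built from dwell-time shares of nested
rectangular regions, and the classification machinery that turns it into a
fear-of-falling (FoF) screen.

## Task geometry

**Calibration.**  For each of forward / backward / left / right, the maximal
excursion over the recorded attempts (normally three) is kept and the target
distance is exactly 0.75 x that maximum.  Attempts must be positive
magnitudes measured from home.

**Target layout.**  Cardinal targets sit at the per-direction target distance
on their axis.  Only four directions are calibrated, so the reachable
movement area is modelled as the rectangle with those four half-extents;
each diagonal target is placed where its 45-degree ray crosses that
rectangle's boundary — at `(±m, ±m)` relative to home with `m` the smaller of
the two adjacent extents (the corner when they are equal).  An elliptical
interpolation would be an alternative; the rectangle is preferred because
the dwell-region construction below already commits to rectangles.

**Scoring.**  A target is hit at the first sample within `target_radius` of
it no more than 10 s (inclusive) after target onset.  After a hit or
timeout, the CoP must stay within `target_radius` of home continuously for
5 s before the next target.  The trial score is the number of hits, 0-8.
The hit radius is nowhere standardised by the protocol (it is the on-screen
target size); the default is 10 % of the mean cardinal target distance and
is configurable.  On timeout the protocol advances to the home phase, which
preserves the fixed eight-phase structure.  A record ending mid-phase is
scored on its completed phases and flagged truncated.

## Preprocessing

The first 5 s of every trial are quiet stance; the home position is the mean
CoP over that prefix (computed from the raw samples), and the prefix is then
removed before analysis.  The remaining signal is low-pass filtered with a
4th-order Butterworth at 10 Hz applied forward and backward
(`scipy.signal.filtfilt`, reflective padding).  Zero-phase filtering is the
posturography norm — a causal filter's group delay would shift region
boundary crossings and bias dwell times — so the effective magnitude
response is the *squared* single-pass response: gain 1/2 (not 1/sqrt 2) at
the 10 Hz cutoff, and an 8th-order-like rolloff.  "4th order" here means the
designed prototype per pass; this is stated explicitly to prevent a silent
halving of the intended order.  Trim-then-filter is the default order of
operations; `filter_before_trim=True` filters across the trim boundary
first, which changes only edge samples.  Non-uniformly sampled input is
rejected rather than resampled.

## Rectangular functional areas and time ratios

The analyzed movement area is the rectangle whose per-direction half-extents
are the calibrated target distances.  Three co-centric rectangles at 33 %,
67 % and 100 % of those extents (the printed percentages, not 1/3 and 2/3),
centred on the per-axis **median** of the analyzed CoP samples, partition
the plane into *disjoint bands*:

* region 1: inside or on the 33 % rectangle;
* region 2: between the 33 % and 67 % rectangles;
* region 3: between the 67 % and 100 % rectangles;
* outside: beyond the 100 % rectangle.

`FTR_i` is the percentage of analyzed samples in region `i` (at uniform
sampling the time share equals the sample share; boundary crossings are not
interpolated), and `FTR_1/2 = FTR_1 / FTR_2`.  The disjoint-band reading —
rather than nested cumulative areas — is forced by the arithmetic of the
published reliability table for these measures: dividing each SEM by its
%SEM/100 yields implied means near 57 / 28 / 15, which sum to about 100, and
under a nested reading FTR_3 would always be near 100.  Design choices worth
stating:

* the centre is the trial median, so samples can fall outside the 100 %
  rectangle; that share is tracked as `ftr_out` and conservation
  `FTR_1+FTR_2+FTR_3+FTR_out = 100` holds to 1e-9 for every trajectory;
* boundaries are closed toward the smaller region (measure-zero on
  continuous data, deterministic on grid data);
* the median is computed per repetition, not pooled over the three
  repetitions (a pooled-median switch exists);
* the 100 % reference is the *target distance* (75 % of maximal excursion),
  because target placement is what defines the movement area; a switch to
  the raw maximal excursion is provided;
* `FTR_2 = 0` makes the ratio `+inf`; it is returned flagged, not raised,
  and the fixed-threshold rule maps it to the low-FoF side;
* repetition averages are component-wise means, and the aggregate ratio is
  `mean(FTR_1)/mean(FTR_2)` by default (ratio of means; a mean-of-ratios
  option exists).  The denominator includes the whole trimmed trial, home
  holds and timeouts included.

## Reliability and convergent validity

Relative reliability is ICC(2,k): two-way random effects, absolute
agreement, average of k = 3 repetitions, computed from the two-way ANOVA
mean squares, `(MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)`.  The 95 % CI is
the standard F-based interval for the single-measure form stepped up with
Spearman-Brown (the construction pingouin and SPSS use; pingouin's ICC(A,k)
is the independent cross-check in the test suite).  Absolute reliability is
`SEM = SD_pooled x sqrt(1 - ICC)` with the pooled SD of all observations —
the most common companion formula; `SEM = sqrt(MS_error)` is available via
`use_ms_error` since the convention is not universal — and
`%SEM = SEM / grand mean x 100`.  Interpretation bands: ICC < 0.40 poor,
0.40-<0.75 acceptable, >= 0.75 high; %SEM > 20 poor, 10-20 acceptable,
<= 10 high.

Correlations use Pearson by default and Spearman when a Shapiro-Wilk gate
(alpha = 0.05) rejects normality of either variable (ordinal scores such as
the Pull Test should be passed as `method="spearman"` directly).  Strength
bands on |r|: < 0.20 negligible, 0.20-0.34 weak, 0.35-0.50 moderate,
> 0.50 strong.  The multicollinearity screen flags predictor pairs with
Pearson |r| strictly above 0.80.

## FoF classification

Subjects are dichotomised by the FES-I total: 16-22 low FoF, 23-64 high FoF
(high is the positive class).  Each candidate index is evaluated as a
single-predictor logistic model (statsmodels Newton MLE, tolerance 1e-8,
<= 100 iterations) with a Wald 95 % CI for the odds ratio.  Complete
separation — for a univariate predictor, non-overlapping class ranges — is
detected up front and returned flagged (`converged=False`, infinite CI)
rather than raised.

ROC analysis computes the AUC by the rank (Mann-Whitney) formulation with
midrank tie handling; orientation is chosen so AUC >= 0.5 and reported,
since an index can mark the positive class by low values (FTR_1/2 does).
The AUC CI is a percentile interval over 2000 class-stratified bootstrap
resamples (seeded); DeLong would be a natural extension.  The operating
point maximises the Youden index J = sens + spec - 1 over observed score
values, reported with inclusive orientation ("high iff value <= c"), ties
broken toward higher sensitivity and then the more extreme cutoff.

Model comparison uses a corrected AIC, lowest wins.  "Corrected AIC" is
ambiguous in the clinical literature; the default is the small-sample AICc,
`-2 lnL + 2k + 2k(k+1)/(n-k-1)`, with Bozdogan's consistent variant
`-2 lnL + k(ln n + 1)` available.  Only the ranking matters downstream.

Cross-validation is stratified fivefold (seeded shuffle; stratification
preserves class imbalance per fold).  Both the logistic model and the
cutoff are re-derived on each training split — reusing the full-sample
cutoff is available but gives an optimistic estimate.  One numerical
convention matters here: the *reported* cutoff is an observed score value,
but a boundary placed exactly on an observed training value guarantees that
any new case just beyond the most extreme training positive is
misclassified; held-out prediction therefore uses the midpoint between the
Youden-optimal value and the next observed threshold, where the training
confusion matrix is unchanged.  Pooled test confusion counts give error,
sensitivity and specificity in percent.

The published fixed-threshold rule is "high FoF iff FTR_1/2 <= 2.83" at
ground level and "<= 2.71" for the 40-cm height condition, both inclusive;
`apply_threshold` implements it for arbitrary cutoffs.

## Synthetic data generator

No public CoP recordings exist for this protocol, so the generator is a
first-class module and defines the study conditions the tests run under.

**Exact-placement dwell mode** (`simulate_dwell_trajectory`) is the oracle
harness for the FTR statistic: given target fractions it places exactly the
apportioned sample counts uniformly inside each band of a *given* RFA set
(fixed centre, no filtering), shuffled in time.  Counts use largest-remainder
apportionment so they always sum to n.  Against the same RFA set the
computed FTRs equal the targets to within 100/n of a point.  This mode is
deliberately circular-free only when the centre is pinned; re-estimating the
median on its output is the realistic mode used end to end.

**LoS-trial mode** (`simulate_los_trial`) generates the full timeline: 5 s
quiet stance, then eight reaches in seeded random order.  Reaches are
critically damped second-order point-mass motions (peak speed set by
`reach_speed`), aimed at the target with endpoint noise for successes
(Bernoulli `hit_probability`) and at a point well short of the target for
failures, which run out the 10-s clock.  Band-limited 4-7 Hz tremor —
below the 10 Hz analysis cutoff, so filtering is meaningfully exercised —
rides on the whole record; during quiet stance and home holds the excursion
from home is clamped inside 0.6 x the hit radius so holds are never broken
by noise.  Ground truth (score, event log) is computed by replaying the task
rules over the generated samples with an independent per-sample loop; the
vectorised scoring engine must reproduce it exactly, which is a test.

**Cohort mode** (`make_cohort`) draws whole cohorts with group-dependent
behaviour.  Trials are *segment-based* dwell trajectories: contiguous
quasi-static holds (duration Exp(1 s), clipped to 0.3-3 s) at anchor points
drawn uniformly inside a region chosen per the profile's dwell fractions,
joined by 0.15-s ramps, over a 110-s task (the natural length of eight
reaches with 5-s home holds and up to 10-s timeouts) after 5 s of quiet
stance.  Independent per-sample placement would be spectrally white and the
10 Hz low-pass would collapse it toward its mean; quasi-static segments
survive filtering, which is why this mode exists alongside the exact
harness.

Default group profiles encode the qualitative clinical picture — low-FoF
subjects park the CoP near the centre and hit targets quickly; high-FoF
subjects guide the CoP poorly and linger in the middle band, with reduced
peripheral excursions:

| parameter | low FoF | high FoF |
|---|---|---|
| dwell fractions (r1, r2, r3, out) | 0.68, 0.15, 0.13, 0.04 | 0.45, 0.36, 0.15, 0.04 |
| reach speed (mm/s) | 60 | 35 |
| endpoint sd (mm) | 1.2 | 2.5 |
| tremor RMS (mm) | 0.5 | 1.0 |
| hit probability | 0.95 | 0.70 |
| FES-I range | 16-22 | 23-64 |

The cohort-wide average of the two dwell profiles sits near (0.57, 0.28,
0.15), the occupancy pattern implied by the published reliability table.
Between-subject and between-trial variability are logistic-normal jitters of
the dwell composition (sd 0.08 and 0.05 on log scale); raised support height
shifts a small dwell mass (1.5 % at 20 cm, 3.5 % at 40 cm) from region 1 to
region 2, a mild postural-threat stiffening.  These constants were chosen
once so that the default profiles satisfy the generator's design contract —
clearly separated FTR_1/2 distributions (ROC AUC >= 0.95 at 19+19 with
fivefold CV sensitivity and specificity >= 90 %) while remaining overlapping
enough that the classification machinery is non-trivially exercised.

**What the simulator does not emulate.**  Realized region occupancies
deviate from the nominal fractions (transition ramps and median re-centring
move a few points of mass between bands); the group *contrast* is the
designed quantity.  There is no inverted-pendulum or neuromuscular dynamics,
no fatigue or learning across repetitions, no sensor noise model, and the
clinical covariates (PT, BBS, TUG, HY) are drawn from group-dependent
distributions rather than a joint subject model.  Passing tests therefore
demonstrate the correctness and determinism of the *measurement and
classification machinery* under controlled dwell structure — not clinical
validity on real patients, whose published headline numbers come from
recordings that are not publicly available.

## Numerical conventions and degenerate inputs

* Sampling must be uniform (max |dt - 1/fs| < 1e-6 s) and strictly
  increasing; NaNs are rejected with counts and indices.
* CSV serialisation uses 17 significant digits; round trips are lossless to
  well under 1e-9 mm.
* The sampling rate is inferred as 1/median(dt) when not declared; a
  declared rate must agree within 0.1 %.
* Zero residual variance in the reliability table collapses the ICC CI to
  the point estimate; an all-constant table is flagged degenerate (ICC
  undefined).
* All-identical ROC scores give AUC 0.5 with a degenerate flag.
* Every stochastic path (simulator, bootstrap, CV folds) is a pure function
  of its seed; identical seeds give bit-identical results.

## Problem sizes

The test suite and the acceptance script run the cohort analysis at
19+19 subjects x 9 trials x 110 s x 100 Hz, the dwell-recovery check at
n = 6000 samples x 100 seeds, ROC/Youden oracles at 200 random datasets of
n <= 50, and the logistic grid oracle at 20 datasets of n <= 16 — sizes at
which every oracle comparison is exact or tightly bounded and the whole
suite completes in well under a minute.
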