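# Methods

## Scope

`swaylab` analyses quiet-stance force-platform recordings: 50 Hz, 30 s per
condition (eyes open / eyes closed), with mediolateral (X) and
anteroposterior (Y) centre-point-of-force (CPF) positions, moments about the
two horizontal axes, and the vertical reaction force. The package covers the
conditioning chain, six time-domain postural-control features, Romberg
quotients, a calibrated synthetic cohort generator, and the cohort-level
statistical battery (balancing, alternating 10-fold cross-validation,
decision-tree sex classification, per-sex age models, rank-sum indicator
tables, RQ analyses).

## Preprocessing

Order of operations: 5-sample median filter → equiripple low-pass FIR →
15 s transient trim (keeping samples 750–1349, i.e. 600 samples / 12 s) →
mean-centring of the positional channels → z-scoring of the weight channel
(the filtered, un-normalised weight is retained for moment computations).

Choices the acquisition spec leaves open, and how they were fixed:

* **Median kernel** — 5 samples (0.1 s). Long enough to delete 1–2-sample
  electrical/contact artifacts, short enough not to smear sway, whose power
  is below a few Hz. Configurable.
* **FIR design** — the spec names edge frequencies (17 / 21 Hz), ≤1 dB
  passband ripple and ≥80 dB stopband attenuation. A Parks–McClellan
  equiripple (minimax / Chebyshev-criterion) linear-phase design meets that
  spec with the smallest tap count; the order starts at a Kaiser-type
  analytic estimate and grows (odd tap counts only, so the group delay is an
  integer) until the measured response on a 4096-point grid satisfies both
  constraints. At 50 Hz this lands on 35 taps, 84.9 dB attenuation, 0.29 dB
  ripple.
* **Single forward pass** with integer group-delay compensation, not
  forward–backward filtering: the printed attenuation describes one pass,
  and a zero-phase double pass would square the magnitude response.
* **Filtering precedes trimming** so both the stance-adjustment transient
  and the filter startup edge fall inside the discarded first 15 s.
* Recordings shorter than 27 s are rejected rather than zero-padded;
  padding would fabricate sway.

## Features

All features are computed on the 600-sample analysis window.

* `cy` — central-95% amplitude range of AP sway: 97.5th − 2.5th percentile
  (linear-interpolation percentiles) of the centred `cpf_y` samples, cm.
  Interpreted as an empirical coverage interval of the samples, not a
  parametric confidence interval.
* `m_my` — mean absolute moment about the AP axis divided by body mass.
  The number is stored as computed (mean |N·m| / kg) without dimensional
  reconciliation; source tables print it in nominal units.
* `zcr_y`, `zcr_x` — strict sign-change counts of the centred positions.
  Zero-valued samples inherit the most recent nonzero sign, so a
  touch-and-return of the axis counts once, never twice; an all-zero signal
  counts zero. `zcr_x` is retained for the correlation table although the
  final six-variable set uses `zcr_y` and `zcr_vx`.
* `zcr_vx` — sign changes of the ML velocity. Velocity uses central
  differences (second-order, phase-neutral; one-sided at the ends).
* `cri_t` — critical time from stabilogram diffusion analysis (below).
* `st_n` — steady-phase sample count (below).
* Auxiliaries for Romberg quotients: total AP sway path Σ|Δy|, mean AP
  velocity, and the full min–max AP range. RQ is eyes-closed over eyes-open,
  so values above 1 mean reliance on vision. The path-based RQ uses the
  literal peak-to-peak path; the 95%-range variant is available separately.

## Stabilogram diffusion analysis

The SDF is the planar mean square displacement
msd(kΔ) = ⟨Δx² + Δy²⟩ over all overlapping sample pairs, every lag from one
sample to 2.5 s (a 12 s record cannot support lags much beyond a fifth of
its duration without excessive variance). The critical point fits ordinary
least-squares lines to the short segment [min lag, b] and long segment
[b, max lag] for every candidate breakpoint leaving ≥4 lag points per side,
keeps the pooled-SSE minimiser (ties to the smaller b), and intersects the
two lines. Fits are flagged degenerate — and excluded from cohort
statistics, never imputed — when the slopes differ by <5% relative or the
intersection leaves (0, max lag].

Resolution limit: with 600 samples and a 2.5 s lag ceiling the estimator
tracks relaxation times up to roughly 1 s and saturates above that; the
monotonicity of the estimate in the underlying relaxation time is therefore
verified on longer records (60 s, 6 s lag ceiling), where it holds cleanly
across τ ∈ {0.5, 1.0, 1.5, 2.0} s.

## Steady-phase detection

The 5-point moving variance (population divisor, centred window) of each
moment channel is summed and divided by mass²; a sample is steady when this
quantity is ≤0.002. The first and last two samples are never steady (the
window needs two neighbours on each side). `st_n` counts steady samples —
sample counts, not interval counts, match the magnitudes (66–225 out of
600) reported for cohorts of this design. `calibrate_threshold` reproduces
the threshold's derivation as the 25th percentile (linear interpolation) of
per-subject mean moving variances of the normalised weight signal.

## Synthetic sway model

No public recordings exist for cohorts of this design, so the generator
stands in for them. Per axis the CPF is a discretised Ornstein–Uhlenbeck
process (stationary sd `sigma`, relaxation `tau`) passed through a one-pole
smoother (`tau_s`) and rescaled to keep the stationary sd exact; white
positional jitter (`jitter`, tremor + sensor noise) rides on the recorded
CPF only. Moments follow an inverted-pendulum coupling
`moment = gain · mass · g · position` plus white control noise gated by a
two-state quiet/active Markov chain; the vertical force wanders slowly
(OU, 16 s relaxation, 60 ms smoothing, 0.5% of body weight).

Why this shape:

* The OU relaxation produces the biphasic SDF (persistent short-term,
  saturating long-term) whose knee the critical-time estimator measures;
  `tau_y` steers `cri_t`.
* A plain discretised OU has near-white increments, so its velocity
  direction-change rate is pinned by the low-pass band edge (~230 per 12 s)
  regardless of `tau`. The smoother lowers that rate and the jitter raises
  it, which makes both zero-crossing rates steerable; physiologically the
  smoother is body inertia, the jitter is tremor plus plate noise.
* The quiet/active gate is what the steady-phase detector sees; the
  stationary quiet fraction steers `st_n`.
* The weight-wander timescales place the lowest quartile of per-subject
  mean moving variance of the normalised weight near the 0.002 threshold,
  reproducing that threshold's published derivation.
* Eyes-open recordings divide `sigma` by a visual gain (default 1.3), so
  Romberg quotients exceed 1 on average; only the ratio is needed.

Defaults for cohort use: masses 83 kg (male) / 70 kg (female) ± 12 kg,
ages uniform within the five bins (65–69, 70–74, 75–79, 80–84, 85–95),
per-subject log-normal jitter with CV 0.10 on the scale parameters. The
packaged cohort specification (`data/table2_cohort.yaml`) carries the
published per-sex, per-age-group sizes and feature-target means; the female
group sizes sum to 2,663 while the published total is 2,664 — the fixture
keeps the per-group values and documents the one-subject discrepancy.

### Calibration

`calibrate_group` matches the mean extracted features of fresh replicates to
a target row by damped multiplicative coordinate descent along the knob
assignments `sigma_y→C(Y)`, `tau_y→CRI(T)`, `gain/noise→M(MY)`,
`quiet fraction→ST(N)`, smoothing/jitter→ZCRs, in that priority. The
zero-crossing rates share knobs with the amplitude and relaxation
parameters and are matched last; they are the features most likely to sit
outside the 10% default tolerance, which is why convergence is judged on
`(cy, cri_t, m_my, st_n)` by default. Later iterations double the replicate
count and anneal the step size. A convergence claim must survive an
independent confirmation batch, and that decision deliberately excludes the
batch that triggered it: iterations whose Monte-Carlo noise leans toward
the target trigger confirmation more often, so pooling the trigger batch
would bias accepted parameters away from the target. The acceptance margin
(default 0.6 of the tolerance) leaves headroom so fresh-seed evaluations
still land inside the tolerance.

Problem sizes used by the shipped analyses: calibration iterates batches of
32 replicates (64 after six iterations) of full 30 s recordings through the
complete pipeline; round-trip checks evaluate 100 fresh recordings; the
scaled-down cohort used by the directional and classification tests has 24
subjects per group. The 100-record evaluation mean of `cri_t` has a
standard error near 3.5%, which dominates the residual spread of the
round-trip results.

## Cohort statistics

* Age strata: inclusive bins 65–69 … ≥85 (70 → group 2, 85 → group 5);
  ages below 65 are out of range.
* Balancing keeps all males and draws, per stratum, a seeded random female
  subset of exactly the male count.
* Folding shuffles within sex, pairs positionally, alternates M/F and cuts
  the pair sequence into 10 folds; leftover pairs stay in training for
  every round (with 1,925 pairs: 192 test pairs per fold, 5 pairs always in
  training).
* "Wilcoxon" comparisons of independent groups are two-sample rank-sum
  (Mann–Whitney) tests; indicator cells are 1 iff p < 0.05, with no
  multiplicity correction (matching the reporting convention of the tables
  this mirrors); a corrected variant can be had by adjusting α.
* Sex classification: binary Gini tree, minimum leaf 20, cost-complexity
  pruning chosen by a small inner 3-fold grid; features are natural-log
  transformed (non-positive values are floored at the column's smallest
  positive value before the log). Sex is coded male = 0 / female = 1.
* Age models: per sex; the headline residual SD is computed on
  cross-validated residuals, with the in-sample value reported alongside
  (the convention is otherwise ambiguous); R²/F come from the in-sample OLS
  fit.
* The RQ battery: correlation between path- and velocity-based RQ, rank-sum
  sex comparisons, 10-fold logistic-regression sex accuracy, one-way ANOVA
  over age groups, and a 5-class decision-tree age-group accuracy over the
  printed bins.

## What the synthetic cohort does and does not show

The generator reproduces the feature *means* of each group, the two-regime
diffusion structure, the steady/active alternation and the published
directional orderings (C(Y) rising with age, M(MY) male > female,
ST(N) female > male). It does not reproduce real within-subject
variability, inter-feature correlation structure beyond what the shared
latent parameters induce, or the overlap between groups — so cohort-level
classification accuracies on synthetic data are systematically higher than
on real recordings and are asserted only against permutation nulls, never
against published real-data accuracies (71% sex accuracy, R² ≈ 0.14–0.15,
4.9–5.2 y residual SD), which require the original cohort.

## Numerical conventions

All indices 0-based, intervals half-open in code-facing docs; X =
mediolateral, Y = anteroposterior. Percentiles use linear interpolation.
Moving variance uses the population divisor. The median filter reflects at
the edges. Degenerate inputs (zero-variance weight, motionless records,
one-regime SDF curves) raise typed errors or flag the affected feature
`None` rather than imputing values.

## Known limitations

* The 12 s analysis window caps resolvable critical times near 1 s.
* `m_my` units are nominal; cross-study comparison requires the same
  convention.
* ZCR targets interact with the amplitude/relaxation knobs; calibration can
  leave them a little outside the tolerance that the other four features
  meet.
* Height is not modelled (not collected in cohorts of this design); body
  mass is the only anthropometric covariate.
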