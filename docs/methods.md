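# Methods

## The problem

A congruency contrast in event-related fMRI (incongruent − congruent BOLD
amplitude) is confounded whenever the two conditions differ in mean RT and
BOLD amplitude itself grows with time on task. `rtbold` implements the three
standard within-participant controls — regression-based RT-equating,
tolerance-window RT-matching, and stride-based RT-subsampling — around a
trial-level GLM, and ships a generator whose ground truth makes the
separation testable: an "RT-only" world (amplitudes linear in RT, no true
condition effect) and a "genuine increment" world.

## Synthetic MSIT generator

**Schedule.** Five runs per participant; each run shuffles 24 congruent,
24 incongruent and 12 fixation trials into a seeded random order. Trials
last 3 s (0.5 s stimulus, 2.5 s fixation), so a run spans 180 s = 90 volumes
at TR 2 s. Onsets are consecutive multiples of 3 s from 0 within each run.

**Behaviour.** RTs are ex-Gaussian (Normal(μ, σ) + Exp(τ), redrawn if ≤ 0),
the standard descriptive RT model. The targets are the condition mean RTs
686.9 ms (congruent) and 969.8 ms (incongruent) and error rates 0.1% / 8.2%.
Only the means are constrained by those targets, so the spread was fixed
once at values typical of interference tasks in youth — conditional SDs of
roughly 150–200 ms:

| condition   | μ (ms) | σ (ms) | τ (ms) | mean = μ+τ | SD = √(σ²+τ²) | P(error) | P(omission) |
|-------------|-------:|-------:|-------:|-----------:|---------------:|---------:|------------:|
| congruent   | 536.9  | 80     | 150    | 686.9      | 170            | 0.001    | 0.005       |
| incongruent | 789.8  | 90     | 180    | 969.8      | 201            | 0.082    | 0.005       |

Omissions (no response: no RT, no accuracy) default to 0.5% per condition so
the overall exclusion fraction lands near the ~2% seen in practice.

**BOLD.** Each responded trial evokes amplitude
`baseline(condition) + rt_slope · RT + increment · [incongruent]`
(defaults: baselines 0, `rt_slope` 0.002 signal units/ms, `increment` 0).
Neural events are impulses at stimulus onset — the dominant convention for
brief (< 1 s) events — convolved with the canonical HRF on a 0.1 s microtime
grid and sampled at the TR. Noise is stationary AR(1) (marginal SD 1.0,
coefficient 0.3) plus three random cosine drift components per run (SD 0.5
each). Omitted trials contribute only the baseline. A volumetric mode
places the same trial signal in every voxel of a sphere on a small
20×20×16 grid (3.75×3.75×3.0 mm voxels, positioned so that the default ROI
centre (2, 16, 46) is a voxel centre), with independent noise per voxel, so
the sphere-ROI code path is exercised at trivial cost. Six smooth
random-walk motion series are synthesized for the 24-parameter nuisance
expansion; they inject no artifact into the BOLD, so the pipeline leaves
motion regressors off by default (a toggle adds them).

The RT–BOLD slope magnitude and noise scale are not constrained by the
calibration targets; 0.002 units/ms against unit noise was fixed once so
that a 28-participant cohort detects the full-data contrast decisively
while single-participant slope estimates remain honestly noisy.

## Trial filtering

Errors (accuracy 0) and omissions (missing RT or accuracy) are excluded
with reasons. Among correct trials, per condition (pooled across runs,
per participant), RTs strictly beyond 3 sample SDs (n−1) from the
conditional mean are excluded as outliers. Bounds are computed once from
the pre-exclusion correct-trial set — a single pass, no iteration — and a
trial exactly at the bound is retained. Outlier bounds use correct trials
only: errors cannot contribute to the conditional means of correct-trial
analyses. A condition with fewer than two correct trials has no defined SD;
the rule is skipped there with a logged warning. Conditional summaries
(mean RT, SD, n) are computed on the retained trials, and these means are
what the design centering and the RT-equating contrast use.

## First-level model

**HRF.** SPM-convention double gamma: gamma-density difference with peak
delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
peak-normalised to 1 so coefficients carry the units of trial amplitudes.
(With these parameters the kernel's true mode sits near 5 s.)

**Design.** Per condition: a main column plus modulators of orders 1–4
whose impulse weights are (RT − conditional mean)^p in raw ms before
convolution — no unit-variance rescaling, so the order-1 coefficient is in
signal units per ms, the scale RT-equating needs. Higher orders are
sequentially orthogonalized against the main column and lower orders within
their condition (SPM convention; switchable). A column that orthogonalizes
to zero (e.g. two trials make the quadratic weights proportional to the
main column) is dropped and recorded in the design metadata, as are classes
with no trials. Error and excluded trials get unmodulated columns. High-pass
filtering is per-run DCT columns with periods > 128 s plus per-run
constants, equivalent to residualising both sides. The matched and
subsampled models are purely categorical: (a) matched/subsampled congruent,
(b) matched/subsampled incongruent, (c) remaining correct trials, (d)
errors, plus the excluded column and nuisance terms.

**Estimation.** OLS, then a single global AR(1) coefficient per signal from
the pooled within-run lag-1 residual autocorrelation, prewhitening of data
and design (first sample of each run scaled by √(1−ρ²)), and one refit —
one Cochrane–Orcutt iteration, the classical approximation to SPM8-era
AR(1) correction; exact REML is out of scope. Columns are internally
rescaled to unit norm for conditioning (polynomial RT columns span ~15
orders of magnitude in raw ms units) and estimates are unscaled afterwards.
Rank-deficient designs raise an error naming the collinear columns via
pivoted QR. Note the small-sample bias of the residual lag-1
autocorrelation (≈ −p/n): with 27 regressors over 450 volumes the AR
estimate sits slightly below the generative 0.3, which is immaterial for
the contrasts but visible if you read `ar1` as an estimator of the noise
parameter.

## RT-control procedures

**Equating.** `congruent_eq = β̂_C + β̂_C,1 · (RT̄_I − RT̄_C)`; contrast
`β̂_I − congruent_eq`; the uncorrected effect `β̂_I − β̂_C` is returned
alongside. Conditional mean RTs are those of the retained trials, the same
means used for centering, so the extrapolation is internally consistent.

**Matching.** Edges join congruent/incongruent trials with |ΔRT| ≤ 10 ms;
the matching maximises pair count. Both RT-sorted lists (ties broken by
trial id, making the output deterministic) are swept with two pointers:
pair when within the window, else advance the smaller. For threshold graphs
on a line this greedy attains maximum cardinality; a brute-force
Hopcroft–Karp oracle guards the claim in the test suite over random
instances. Trials are pooled across runs; each trial enters at most one
pair (the procedure picks a single partner per trial). Mean matched RT
difference is bounded by the window by construction.

**Subsampling.** Per condition with n retained trials and target k (the
matched-pair count), indices ⌊j·n/k⌋ for j = 0..k−1 on the RT-sorted list —
one reading of "uniform intervals"; a centred variant ⌊(j+½)·n/k⌋ is
available behind a flag. This preserves the RT distribution shape and hence
the behavioural effect while equating trial counts with the matched set.

## Group level

Summary-statistics random effects: one congruency effect per participant
per analysis, then a two-tailed one-sample t (df = n−1, α = .05). The 2×2
congruency × sampling-method ANOVA is computed through its exact algebraic
identities — interaction F(1, n−1) = (paired t on effect differences)²,
congruency main effect = (one-sample t on the mean of the two effects)² —
with the degenerate identical-inputs case defined as F = 0. The age ANCOVA
regresses effects on mean-centred age (statsmodels OLS): the intercept
tests the congruency effect at the mean age, the slope its age modulation;
constant ages raise, a zero-residual fit warns. Ages in simulated cohorts
are drawn uniformly on 8–18 years. ROI membership uses voxel centres
(no partial-volume weighting) on an axis-aligned world-mm grid.

## Problem sizes in the shipped checks

The calibration and recovery checks run at the study's native size
(28 participants × 5 runs). The null-calibration check (rejection rate of
the equated and matched group contrasts under RT-only truth) uses 500
simulated experiments of 12 participants × 2 runs each: the calibration of
a one-sample t does not depend on cohort size, and this size keeps the
500-replicate estimate cheap while its binomial tolerance (±1.9 percentage
points around 5%) stays meaningful. Parameter-recovery bias is averaged
over three 28-participant cohorts (84 first-level fits).

## What the synthetic data do and do not show

The generator reproduces the features the analyses are sensitive to —
condition RT distributions, error/omission rates, trial scheduling, linear
RT–BOLD coupling, serial correlation, slow drift — but not scanner physics
(physiological noise beyond AR(1), motion artifacts coupled into the
signal, spatial autocorrelation, susceptibility dropout) or behavioural
non-stationarity (fatigue, learning, post-error slowing). Passing tests
therefore certify the *statistical machinery* — that the estimators are
unbiased, calibrated and separate RT confounds from genuine effects under
the stated model — not that real pMFC data satisfy that model. Voxelwise
whole-brain inference (topological FDR, cluster correction) and fMRI
preprocessing (slice timing, realignment, normalisation, smoothing) are
deliberately out of scope.

## Known limitations

- The AR(1) scheme is a one-iteration global approximation; heavy serial
  correlation or short runs will leave residual autocorrelation.
- The matching window is a hard threshold; no caliper/propensity
  generalisation is provided.
- `ancova_age` fits a linear age term only.
- The volumetric mode is a functional miniature (a few thousand voxels),
  not a realistic acquisition grid.
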