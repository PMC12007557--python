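# Methods

This note documents the models, parameter choices, and numerical decisions
behind `chordlearn`, and what the synthetic-data tests do and do not
establish about real data.

## Task model

A *chord* is a simultaneous combination of 1–4 finger presses in fixed
finger order (pinky, ring, middle, index). Of the 15 nonempty
combinations, two (1101 and 1011) are excluded as too difficult to press
simultaneously, leaving 13. A *sequence* is 5 distinct chords with Hamming
distance exactly 3 between consecutive chords (3 fingers change per
transition). The sequence search is an exhaustive depth-first enumeration
over the transition graph — the full pool (576 sequences) is small enough
that no stochastic search is needed; a seed only shuffles output order.

Configurations (3 trained + 6 untrained sequences) must share no ordered
chord transition between the two sets. A transition is *ordered* (a→b)
because execution order matters. Subject to that hard constraint, the
partition search minimises a lexicographic objective: first the number of
chords shared between the sets, then the L1 distance between the two sets'
normalised per-finger press frequencies. The search enumerates trained
subsets exhaustively below a configurable cap and otherwise draws seeded
random candidates; the untrained complement is chosen exhaustively when
small, else greedily by incremental objective. The default pool admits
partitions with zero shared chords.

Scanner sessions present 2 trained + 2 untrained sequences, 8 trials each
per run, 5 runs (160 trials), with no two consecutive trials of the same
sequence. Ordering uses a seeded greedy scheduler that draws uniformly
among ids with remaining trials (excluding the previous id) and forces an
id once its remaining count saturates the remaining slots; this terminates
without retries for balanced designs. Which 2 of 3 trained sequences are
tested is a seeded draw; untrained pairs cycle deterministically across
sessions (0/3/6, 1/4, 2/5). The trial window is 6.6 s (1 s fixation + 3
preparation beats + 5 execution beats at 0.7 s/beat) and a 6 s stretch
pause follows every 8 trials, so a run fits comfortably in 400 volumes at
TR 1.2 s.

Inter-trial intervals are exponential with mean 7.4 s truncated to
[6.0, 9.2] s. The truncated mean of Exp(λ) on [a, b] is
1/λ + (a e^{−λa} − b e^{−λb})/(e^{−λa} − e^{−λb}); the rate is calibrated
by Brent root-finding so this equals 7.4 s (a quadrature cross-check
agrees to 1e−6). Targets above the interval midpoint (7.6 s) are
unreachable and rejected.

## Behavioral scoring

Presses are clustered into 5 chords at the 4 largest inter-press gaps
(ties to the earliest gap); trials with fewer than 5 presses are *missed*.
A trial is correct iff the nth performed key set equals the nth target
chord, in order. Paced verdicts compare MT to the prescribed
(5−1) × 0.7 = 2.8 s with a ±10 % window.

MT is defined as last-chord mean time minus first-chord mean time. The
endpoints are not dictated by the task logs themselves; this definition is
consistent with the 4-interval structure (4 × 0.7 s = 2.8 s) and is
recorded in `behavior.mt_definition`. Session statistics discard the first
10 presented trials of each sequence (performance is unstable early in a
session); a documented switch (`discard_counts_incorrect=False`) instead
discards the first 10 *correct* trials, since either reading is plausible.
The default counts presented trials. Error counts are taken before the
discard. IPI consistency is the Pearson correlation of the 4-interval
vectors of trials t and t+lag (lag 1..9), averaged over pairs;
zero-variance vectors make the correlation undefined, so those pairs are
skipped and counted rather than imputed.

Exclusion rules use the Tukey upper fence Q3 + 1.5 IQR with quartiles by
linear interpolation (numpy's default, type 7), applied per
session × sequence across subjects for behavioral error counts and across
runs for framewise-displacement summaries. "1.5 IQR above the third
quartile" is the standard reading adopted for both.

## Pattern estimation

The trial GLM is ordinary least squares per voxel with one regressor per
trial: an impulse at trial onset convolved with a canonical double-gamma
HRF (gamma-density difference, peak delay 6, undershoot delay 16, ratio
1/6, unit scale; peak-normalised), evaluated on a 12× oversampled grid and
read out at volume times. The BOLD simulator uses the same design-matrix
code, so the noiseless round trip is exact by construction — the test of
that identity checks the solver, not the construction, which is verified
separately (HRF shape, onset handling). Temporal autocorrelation is not
modelled; with trial spacing of ~14 s and a high-pass filter this mainly
costs efficiency, not bias, but it is a simplification relative to
GLS-based packages. Nuisance columns (constant, Legendre drift, motion and
its first difference) are optional; per-trial derivative regressors are
not included.

High-pass filtering projects out a discrete-cosine basis with periods
longer than the cutoff (k = 1 .. ⌊2·N·TR/cutoff⌋, default 90 s) plus the
mean.

The noise covariance is (1−λ)S + λ diag(S) with S the sample covariance of
GLM residuals. When λ is not supplied it is the analytic plug-in weight
for the diagonal target (summed sampling variances of off-diagonal entries
over their summed squares, clipped to [0, 1]) — small when off-diagonal
structure is well estimated, near 1 when it is noise. Prewhitening
multiplies patterns by the inverse symmetric square root of the
covariance, computed by eigendecomposition with an eigenvalue floor of
1e−10 × trace/p; genuinely indefinite inputs are rejected.

## Second-moment decomposition and crossnobis

G[t₁,t₂] = ⟨V_{t₁}, V_{t₂}⟩/P with P the voxel count (the same
normalisation as the crossnobis denominator, so entries are comparable
across ROI sizes). Only correct trials from eligible runs enter — a run
is eligible when each of the 4 tested sequence types has ≥ 3 correct
trials — via a single shared pre-filter.

The eight components are binary matrices built from trial metadata:
all-ones intercept; same-run; both-trained; both-untrained; same sequence
type within the trained (untrained) class — within-run same-type pairs
included, since the same-run contribution is the separate additive H_R
term; and diagonal indicators of trained/untrained trials. Coefficients
are fit by NNLS on the vectorised full matrix (each off-diagonal entry
effectively counted twice, the diagonal once). Linear dependence of the
basis on a given design (e.g. a single run, where H₀ = H_R) triggers an
identifiability warning. The variability index is s = log α for the two
diagonal coefficients; a coefficient clamped at zero makes s undefined and
is flagged rather than returned as −inf.

The synthetic pattern generator inverts this model: each α is the variance
of a shared standard-normal voxel vector (global, per-run, per-class,
per-type) or of per-trial noise, so E[G] = Σ αᵢHᵢ holds exactly and NNLS
recovery can be tested against the generating weights. Acceptance-level
recovery (5 runs × 4 types × 8 trials, 2,000 voxels, 100 replicates)
shows per-component relative bias below 5 %.

Crossnobis sums ⟨dᵢ, dⱼ⟩ over ordered run pairs i ≠ j, where dᵢ is the
difference of run-mean patterns, divided by R(R−1)P. Because the folds are
independent runs the estimator is unbiased: its mean is zero for
identically distributed conditions and negative values are reported as-is,
never clipped. Pair values are averaged within three categories
(trained–trained, untrained–untrained, trained–untrained).

Decoding uses a linear SVM (scikit-learn `SVC(kernel="linear")`) with
leave-one-run-out outer folds; C is selected per outer fold by inner
leave-one-run-out cross-validation over a log-spaced grid with 5 points
per decade spanning 1e−2..1e1 (ties to the smallest C). Calibration on
no-signal data uses *within-run* label permutation: permuting across runs
unbalances the classes inside CV folds and produces the well-known
below-chance bias, whereas exchangeability within runs preserves per-run
balance and centers the null at 0.5.

## Longitudinal models

Five session-trend shapes over sessions t = 0..6 (midpoint m = 3,
final T = 6), all columns mean-centered:

| model | columns |
|---|---|
| linear | t |
| asymptotic | 1 − ((t−m)/m)² for t ≤ m, then constant 1 |
| inverse_quadratic | 1 − ((t−T)/T)² |
| quadratic | t, t² |
| cubic | t, t², t³ |

The "asymptotic" and "inverse-quadratic" shapes are distinguished only
verbally in their source description; the forms above satisfy the stated
properties (concave rise; the asymptotic one flat after mid-training) and
are pluggable should a different parameterisation be preferred.

Models are random-intercept mixed models (statsmodels `MixedLM`). Random
slopes are omitted: with 7 sessions they frequently yield singular fits
without materially changing fixed effects; singular fits are reported via
a flag, never hidden. BIC = k ln n − 2 ln L with n the row count and k
counting fixed effects plus the random-intercept and residual variances;
comparisons use maximum-likelihood fits because REML likelihoods are not
comparable across fixed-effect structures, while REML remains the default
for coefficient inference. Optimisation uses BFGS with a Powell fallback
on linear-algebra failures. Ties break toward fewer parameters, then
listing order. Interaction tests are Wald tests on the ML/REML
coefficients (large-sample; no Satterthwaite correction — at the row
counts used here the type-I error is 0.045–0.05 over 1,000 null
replicates). An lme4 cross-check (via Rscript) verifies the ML BIC to
0.01.

The trend-recovery simulations use one fixed coefficient vector per model
(`synthetic.DEFAULT_TREND_COEFFICIENTS`), sized so the trend is comparable
to the noise scale (random-intercept SD 0.5, residual SD 0.5) — visible
but not overwhelming, as in behavioral learning data. At n = 200 subjects
each generating model is re-selected by BIC in ≥ 90 % of replicates.

FDR control is Benjamini–Hochberg step-up (statsmodels). ICC is the
two-way random-effects, absolute-agreement, single-measure ICC(2,1)
computed from the ANOVA mean squares, with subject, timepoint, and error
variance components reported (negative component estimates are truncated
at zero in the report; the ICC itself is not truncated).

## Synthetic data: scope of the evidence

The behavioral generator produces exponential learning curves
(a + b·e^{−ck}), evenly spaced chords with Gaussian within-chord jitter,
and chord-substitution errors; it terminates at exactly 20 (unpaced) or 5
(paced) correct trials per sequence. It does not model within-trial
tempo drift, anticipatory errors, or timing-based errors (a configurable
alternative to chord substitution is noted but substitution is the
default). The BOLD generator is the GLM's exact forward model with white
noise — no autocorrelation, drift (beyond an optional nuisance test), or
motion artifacts; the longitudinal generator has Gaussian random
intercepts only. Passing tests therefore establish correctness of the
estimators under their own assumptions and calibration under clean nulls;
they do not establish robustness to realistic fMRI noise, which the
shrinkage/prewhitening path only partially addresses.

## Problem sizes

The test and acceptance suites use the study's design sizes where they are
cheap (160-trial sessions, 2,000 voxels, 100-replicate recovery loops,
1,000-replicate calibration loops, n = 200-subject model-selection runs)
and smaller replicate counts for auxiliary property checks; each file
states its sizes inline.
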