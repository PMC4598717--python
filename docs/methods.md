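# Methods

`plastimap` reimplements, at desk scale, the analysis chain used to show
that an effective cognitive intervention normalizes both the level and the
spatial pattern of task-evoked brain activity in children with mathematical
learning disability (MLD), and that the amount of pattern change predicts
behavioural improvement. Because no raw data from such studies are
available here, the package's empirical claims are calibration claims:
every inferential stage is exercised against a synthetic cohort generator
whose ground truth is stored, and the test suite asserts that each stage
recovers what was put in and errs at its nominal rate when nothing was.

## The synthetic cohort

`synth.SimulationConfig` encodes the study design: two groups (MLD, TD) of
15 children, scanned before and after tutoring, two runs per session, 12
Addition and 12 Control trials per run. Each trial occupies a 10 s slot
(0.5 s fixation + 9.5 s response window); six 10 s rests are interleaved at
jittered positions at least two trials apart; the run length (300 s, 150
volumes at TR = 2 s) is derived from this schedule. Per-trial correctness
is Bernoulli with the child's latent accuracy, so "correct-only" GLM
sub-conditions vary realistically.

A session-level activation map (units of a single-subject *t* statistic)
for subject *s* in session *k* is

    map_sk = a_s * [ sum_task  b_j  P_j(v)  +  sum_aberrant A_srk  Q_r(v) ]
             + sigma_subj * S_s(v) + sigma_noise * E_sk(v)

where `P_j`, `Q_r` are Gaussian foci (sigma = radius/2; defaults place four
aberrant foci of 14 mm radius and two shared task foci of 10 mm on a
24 x 28 x 24 grid of 2 mm voxels inside an ellipsoidal brain mask), `a_s`
is a per-child multiplicative activation strength (1 +/- 0.30, floored at
0.3), `S_s` is a child-specific *stable* smooth pattern present in both
sessions (sd 1.2), and `E_sk` is session noise (sd 0.5), both smoothed to
6 mm FWHM. Aberrant amplitudes: `A_s,pre = pre_effect_r * a_s` for MLD
(defaults 4.5, 3.2, 5.2, 2.9), 0 for TD; `A_s,post = A_s,pre * retention_s`
with retention = clip(0.2 + 0.35 u_s, 0, 1) shared across regions. The
aberrant foci carry no TD baseline: the group-difference mask by
construction selects voxels where controls barely respond, which is what
lets the z-scored *pattern* (not just the level) separate the groups.

Two design points deserve emphasis because they were genuinely open:

- **Variance budget.** Most non-effect variance is placed in the stable
  subject pattern rather than session noise. Both enter the
  between-subject variability that limits classification identically, but
  they act oppositely on the Brain Plasticity Index: session noise is
  uncorrelated across sessions and directly corrupts the pre/post
  correlation each BPI is built from, whereas the stable pattern raises the
  baseline correlation and thereby *shrinks* the sampling error of r
  (which scales with 1 - r^2). With the default budget the computed BPI
  ranks children by their true normalization magnitude at Spearman
  rho ~ 0.8.
- **Coupling and measurement reliability.** The latent normalization
  magnitude and the latent accuracy gain are drawn from a bivariate
  Gaussian with correlation rho (default 0.6); the gain is pushed through a
  logistic squash that keeps accuracy in (0, 1) while staying first-order
  additive at the operating point. Observed accuracy is a binomial draw
  over the 24 Addition trials per session, contributing ~0.13 sd of
  measurement noise to the observed gain; the true gain spread (0.15) is
  set so that true variance dominates measurement noise, the regime a
  mid-0.5 observable BPI-gain correlation implies. Even so, attenuation is
  real: at rho = 0.6 the median recovered Pearson r across cohorts is
  ~0.3-0.35, inside the Fisher-z 95% sampling band of 0.6 at n = 15 but
  well below it in expectation — a deliberate reminder that small-sample
  brain-behaviour correlations are noisy estimates.

Behaviour: baseline accuracy ~ N(0.72, 0.07) for MLD and N(0.85, 0.05) for
TD; gains ~ N(0.15, 0.15) and N(0.02, 0.04). Reaction times (ms) combine a
group-session mean (MLD 3400 -> 3250; TD 3300 -> 2800), a stable per-child
offset (sd 800), a session fluctuation (sd 250), and trial-level
measurement error — chosen so the within-group speed-up is strong for TD
and weak for MLD while the groups never differ reliably, as in the study
population this emulates.

`maps` mode generates the session maps directly and is the default for
cohort-scale simulation studies. `bold` mode forward-simulates full 4-D
runs: condition regressors are 9.5 s boxcars convolved with the canonical
HRF, multiplied by Addition/Control amplitude fields (Control = 0.3 x
Addition); noise is AR(1) in time (rho 0.3) with spatially smoothed
innovations; motion traces are slow random walks into which displacement
spikes (2-3.5 mm, paired with 6-12% global-intensity excursions) are
injected at `motion_spike_rate`. All randomness flows from one
`SeedSequence`, one spawned stream per subject, so cohorts are
bit-identical under a fixed seed.

## Despiking and inclusion rules

Scan-to-scan displacement is the Euclidean norm of the frame-to-frame
change in (x, y, z, 65 mm * pitch, roll, yaw in radians); a per-axis
variant is available by flag. Volumes with displacement > 1.562 mm (0.5
voxels at the study's native resolution) or global signal deviating > 5%
from the run median (reference selectable: median or previous volume) are
replaced by linear interpolation of the nearest clean neighbours, edge
volumes by copying. Flagging and repair iterate to a fixed point and the
realignment parameters of flagged volumes are interpolated too, making the
operation idempotent (a despiked run contains nothing left to flag). A run
in which every volume is flagged is an error, not a silent repair.
Subjects are excluded when >= 20% of frames were interpolated or in-scanner
accuracy is not strictly above 50%; the per-criterion reasons are reported.

## GLM

Four sub-conditions (Addition/Control x correct/incorrect) each contribute
a 9.5 s boxcar convolved with the canonical double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 6:1, 32 s support, 0.1 s oversampling) plus a
temporal derivative orthogonalized to its parent column; rests are
unmodelled; a discrete-cosine drift basis (128 s cutoff) and intercept
complete the design, which is rank-checked with offending columns named.
Estimation is voxelwise OLS (df = volumes - rank); AR(1) noise is present
in the generator but not prewhitened — the null-calibration test therefore
runs with temporally white noise, and mild anticonservatism under
autocorrelation is a known, documented deviation. The contrast of interest
is Addition-correct minus Control-correct over HRF columns only; per-run
contrast maps are averaged across runs (t-averaging available by flag).
Noiseless identifiability is exact to 1e-6 because the simulator and the
design matrix share one convolution routine — that test pins the forward
and inverse models to each other, not to an external constant.

## Group inference

Voxelwise two-sample (pooled variance) or paired t; an optional
centred-covariate linear model (intercept + group + covariate) returns the
t of the group term, used for the "controlling for baseline accuracy"
analysis. Smoothness is estimated from the gradient variance of
standardized within-group residuals, FWHM = dx sqrt(4 ln 2) sqrt(var r /
var dr): ~1.18 voxels for white noise and within 5% for a 6 mm kernel on
this grid. The cluster-extent threshold simulates n_sim null fields (white
noise smoothed to the estimated FWHM, standardized in-mask), thresholds at
the voxel height p in both directions, records the maximum cluster size
(26-connectivity default; 6/18 selectable), and returns the smallest extent
whose exceedance probability is <= alpha. n_sim defaults to 10,000 and the
simulation is seeded; alpha below the 1/n_sim resolution is an error.
Because the data field is a two-sample t statistic, not a Gaussian field —
its slowly varying denominator gives heavier cluster-size tails at low df —
the engine has a group-aware mode that simulates 2n smoothed noise maps and
computes the actual t statistic per iteration; the pipeline uses it
(single-field Gaussian simulation remains available and is what the
zero-smoothness brute-force oracle checks). The resulting extent for the
default cohort geometry is ~90 voxels at height p < 0.01, alpha = 0.01
(vs ~78 under the Gaussian approximation) — a function of the mask and
smoothness, not a constant of the method.

The Bayesian complement is a robust two-group model on ROI betas: Student-t
likelihood per group, normal priors on means (sd = 1000 x pooled sd),
log-uniform priors on scales over (pooled sd / 1000, x 1000), shared
normality parameter nu with nu - 1 ~ Exponential(mean 29), sampled with an
affine-invariant ensemble (emcee, 16 walkers; 400 burn + 1200 kept by
default). Reported: posterior mean difference, 95% highest-density
interval, effective sample size, and a convergence flag (never a silent
failure). On null data the 95% HDI covers zero in ~95-98% of replicates —
mildly conservative, as expected for weakly-informative robust models at
n = 15.

## Pattern classification and permutation inference

Features are session t-maps masked with the pre-tutoring group-difference
cluster mask and z-transformed per subject over mask voxels (population
divisor; the sample-divisor variant only rescales each row by a common
constant and is exposed by flag). The classifier is a linear C-SVC with
C = 1 evaluated by leave-one-out cross-validation; with a precomputed Gram
matrix the fold models are fitted through scikit-learn's low-level libsvm
binding, which a dedicated test holds to exact prediction agreement with
the public `SVC` estimator; the public path is the automatic fallback.
The permutation test shuffles labels once per permutation (reused across
folds, preserving exchangeability) and recomputes the *full* LOOCV; the
p-value uses the +1-smoothed estimator, so p is never 0 and its floor is
1/(n_perm + 1).

Under the default cohort the pre-tutoring patterns classify at ~0.91 mean
LOOCV accuracy (significant in every tested seed) while post-tutoring
accuracy falls to ~0.43 and stays non-significant in >= 90% of seeds —
the machine analogue of normalization. The residual 0.2-retention signal
means occasional post-session significance is expected and honest: the
criterion is a rate across seeds, not a guarantee per cohort.

## Brain Plasticity Index

BPI = 1 - Pearson r between the z-transformed pre and post in-mask
patterns (same mask and z-convention as the classifier; t-maps assumed, as
for the classifier features). It is bounded in [0, 2], symmetric in its
arguments, invariant to positive affine rescaling of either map, and
antisymmetric under negation. The BPI-gain relation is a Pearson
correlation with t-based two-sided p; the baseline-covariate screen
correlates each standardized baseline measure against the gain,
uncorrected, with listwise deletion and retained-n reported.

## Behavioural statistics

Accuracy pools correct Addition trials over a session's runs; RT is the
mean over runs of the per-run median of correct-trial RTs (ms; median ties
resolved by the mean of the central pair, numpy convention). Effect sizes
derive from the t statistic: d = t / sqrt(n) paired, t sqrt(1/n1 + 1/n2)
independent — the conversion, not raw-moment d, because it reproduces the
printed worked examples exactly at 2 dp. Normality checks are one-sample
Kolmogorov-Smirnov with moments estimated from the data; since estimation
invalidates the naive K-S null, the Lilliefors-corrected p is the default
and the naive variant is exposed for comparison.

## Problem sizes and numerical choices

Simulation studies in the test suite use: 400 replicates at n_perm = 199
for permutation-test calibration; 50 seeded cohorts for the
normalization-detection rate; 300 cohorts for coupling recovery; 200
noise-only cohorts for the family-wise error rate of the full cluster
pipeline with k_min calibrated once at 2,000 group-aware simulations (the per-study
calibration a practitioner would run, reused across cohorts whose
smoothness differs only by sampling noise); 200 replicates at reduced MCMC
length (300 + 800 steps) for Bayesian coverage. The acceptance script runs
the headline pipeline at n_perm = 1,999 and n_sim = 10,000. All of these
are seeded; reruns are exactly reproducible.

## What passing tests do and do not show

The generator produces Gaussian, stationary, homoscedastic fields with
known foci; real BOLD data have physiological noise, susceptibility
dropout, imperfect registration, and aberrations that are not spherical
Gaussians. Calibration here therefore demonstrates that the *procedures*
are implemented correctly and err at nominal rates under their own
assumptions — not that those assumptions hold in any particular dataset.
Known limitations: no prewhitening by default (OLS); cluster inference
assumes a single pooled smoothness; the BPI is computed on the same mask
used to demonstrate group separation (as in the design this emulates, a
selection the pre/post comparison does not itself bias); and the
behavioural model treats accuracy as exchangeable Bernoulli trials,
ignoring item difficulty.
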