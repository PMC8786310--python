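# Methods

This note documents the models, conventions and numerical choices behind
`prepmvpa`, and what the synthetic-data tests do and do not establish about
real data.

## Task and design model

A session consists of functional runs of a delayed go/no-go finger-press
task.  Each run holds 30 trials — 6 trial types (3 single fingers: thumb,
middle, little; and 3 multifinger-sequence types) x 5 repetitions, exactly
3 go and 2 no-go per type, in uniformly random order.  Preparation delays
are drawn i.i.d. from {4, 6, 8} s with probabilities {0.56, 0.30, 0.14},
intertrial intervals from {1, 2, 4, 8, 16} s with probabilities
{0.52, 0.26, 0.13, 0.06, 0.03} (the halving pattern; these sum to one).
The movement phase lasts 2.5 s, the reward phase 0.5 s, and 10 s of rest
pad both ends of every run.  Within-run ordering is not constrained beyond
the per-type counts; whether ordering should be counterbalanced across runs
is an open design question, and we randomize.  Sequence-type trials are
carried through design and GLM (they contribute realistic collinearity and
the full 18-regressor layout) but their patterns are not analyzed; the
analyzed conditions are the 6 single-finger conditions (3 fingers x
{planning, execution}).

## Hemodynamic response

The impulse response is a difference of two gamma densities.  Its two
stated landmarks — response maximum at 5 s, post-stimulus undershoot
minimum at 10 s — are enforced exactly: both gamma shapes are solved from
the two stationarity conditions h'(5) = 0, h'(10) = 0 by a numerical
root-find at construction time.  With the response lobe at 1 s dispersion
and an undershoot amplitude ratio of 1/6, a trough as early as 10 s is
geometrically unattainable for a broad undershoot lobe (scanning shapes at
unit dispersions places the earliest attainable trough near 13.7 s), so the
undershoot dispersion defaults to 0.13 s.  The resulting response has a
~10% relative undershoot — canonical in depth, narrower in time than the
SPM default, which is the price of the 5 s/10 s landmark pair.  Responses
are normalized to unit peak; regressors are 2 s boxcars at each phase onset
convolved on a 0.1 s grid (avoiding aliasing of the boxcars) and decimated
to TR = 1 s.

## VIF design scoring

For regressor j, `VIF_j = [(X'X)^-1]_jj / [(X_iso'X_iso)^-1]_jj`, where
X is the full single-run design matrix and X_iso contains regressor j and
the run intercept only.  The noise variance cancels in the ratio, every
VIF is >= 1, and VIF = 1 iff the regressor is orthogonal to the rest of
the (intercept-centered) model.  The intercept is always part of the
isolation model because it is always estimated.  Design scoring defaults to
the 12-regressor model (6 trial types x planning/movement phases) — the
regressor set whose separability the design optimization targets — with the
18-regressor go/no-go-split model (12 go + 6 no-go planning) available for
estimation.  `optimize_design` is plain random search: the candidate with
the lowest mean VIF over the targeted regressors wins; no structured
optimizers, by design.  Under the task distributions, sampled designs score
a mean VIF of about 1.11 and best-of-20 winners about 1.08.

## GLM, noise covariance, prewhitening

Estimation is run-wise ordinary least squares; residual degrees of freedom
are T_r minus the design rank.  The voxel noise covariance pools residual
cross-products over runs weighted by df (one prewhitener per dataset
maximizes stability; a run-specific covariance can be passed through the
same interface by calling the estimator per run).  Regularization shrinks
toward the diagonal, `Sigma* = (1-λ)S + λ diag(S)`, with λ set by the
analytic optimal-shrinkage coefficient on the correlation scale
(Schafer–Strimmer form: the ratio of the summed sampling variances of the
off-diagonal correlations to their summed squares, clipped to [0, 1]); λ is
reported and overridable.  scikit-learn's Ledoit–Wolf estimator shrinks
toward a scaled identity rather than the diagonal, hence the in-package
implementation.  Whitening uses the symmetric (eigendecomposition) inverse
square root, which is basis-independent; temporal autocorrelation is not
modeled (the simulated noise is white) — a documented limitation for real
data.

## Crossnobis distances

With prewhitened run-wise patterns, the dissimilarity between conditions i
and j is the average over ordered run pairs m != n of `δ_m' δ_n / P`,
δ = pattern_i − pattern_j, P the voxel count (distances are per voxel).
Because the two factors carry independent noise the estimator is unbiased
— zero expectation under pure noise, negative values possible.  "Any other
run" admits two readings; the all-ordered-pairs average is the default and
the leave-one-run-out form (each run crossed with the mean of the others)
is offered too — the two are algebraically identical here, which the test
suite verifies.  The expected crossnobis RDM relates 1:1 to the
second-moment matrix G of the true patterns via
`d(i,j) = G_ii + G_jj − 2 G_ij`.

Searchlights are fixed-count (100 voxels) nearest-neighbor neighborhoods on
synthetic grids or arbitrary point clouds; the nominal disc radius is kept
as metadata and nodes whose members spill past it are flagged.  Real
cortical meshes are out of scope — the statistic, not the mesh, is what
this package exercises.  Classical (Torgerson) MDS double-centers the RDM,
placing the across-condition mean pattern at the origin; negative
eigenvalues (the RDM need not be Euclidean-realizable) are truncated in the
projection and flagged.  The peak-location comparison between planning and
execution maps uses a one-sample Hotelling T² on paired coordinate
differences with the standard F conversion, `F = (n−p)/(p(n−1)) T²`.

## Pattern component correlation models

The 6 x 6 second moment is
`G(r, θ) = a_p J_p + a_e J_e + s_p I_p + s_e I_e + r √(s_p s_e) X_pe`:
phase-common components (all-ones blocks), finger-specific components
(identity blocks), and a cross-phase coupling of matching fingers fixed at
correlation r.  G is PSD for all r in [0, 1] and non-negative variances.
Each model has exactly five free parameters — four signal variances plus
the noise variance — optimized as logs (positivity by construction) with
L-BFGS-B and an analytic gradient.

The marginal likelihood treats voxels as i.i.d. columns:
`Y_v ~ N(0, V)`, `V = Z G Z' + σ²_ε I`, with voxel means *not* removed
(second-moment convention).  Run-wise mean patterns are treated as fixed
effects: each run's six rows are projected onto the orthonormal complement
of the constant vector before evaluation, which keeps the likelihood exact
on the reduced space (the noise stays white under the orthonormal
projection).  One consequence is that a_p and a_e are identified only
through their sum — centering maps both phase-mean components onto the same
planning-vs-execution contrast — which is harmless because inference
concerns r.  The phase means across fingers are retained.  σ²_ε is shared
across runs.  Nearly singular V is Cholesky-factorized with escalating
jitter and a warning.

Fits use a data-driven moment start (cross-run second-moment estimates,
floored at a small fraction of the data scale) plus a generic start;
grid sweeps warm-start each model from its neighbor's optimum and fall
back to the moment start when the warm start is worse.  A terminated line
search at negligible gradient norm (< 1e-3) counts as converged — it
happens when the warm start already sits at the optimum.

The correlation grid defaults to 100 models equally spaced on [0, 1]
including both endpoints (step 1/99); a 101-point grid with exact 0.01
steps is available, honoring the two natural readings of "models from 0 to
1 in equal steps".  Group inference centers each subject's log-likelihood
curve on its across-model mean (rows sum to zero; differences are log-Bayes
factors).  Leave-one-subject-out selection picks the argmax of the mean
curve over N−1 subjects (ties break toward the lowest r, deterministically)
and records the left-out subject's log-likelihood at that winner; each
model is then compared against this best-model vector with a one-sided
paired t-test at α = 0.05.  The group correlation estimate is the mean and
SEM of per-subject argmax correlations, with a two-tailed one-sample t-test
of the best-vs-zero-model log-likelihood difference.

Why the grid instead of correlating patterns directly: raw correlations of
noisy patterns are attenuated toward zero, so even perfectly correlated
planning/execution patterns yield sample correlations well below one.  The
likelihood grid accounts for the noise explicitly; the test suite
demonstrates both the attenuation (raw r ≈ 0.65 at true r = 1 under low
SNR) and the approximate unbiasedness of the grid argmax.

## Behavioral control analysis

Force traces are sampled at 2 ms (200 Hz transducers), smoothed with a
Gaussian kernel of 9.42 ms FWHM — interpreted as milliseconds, the only
reading compatible with 2 ms samples and 10 ms bins — and averaged in
10 ms bins.  Per block and condition, the time-averaged force of each
finger is computed per trial over the phase being compared (preparation
window for planning conditions, using all trials since the hold is
identical until the cue; movement window of go trials for execution), and
the across-trial mean and SD form a 10-dimensional condition pattern
(60 x blocks in total).  The across-trial (rather than within-trial) SD is
a documented choice where both readings exist.  Patterns are prewhitened in
the 10-dimensional feature space with the same shrinkage rule as the voxel
covariance, estimated from across-block residuals after removing condition
means — whitening the literal 60-dimensional block vector would mix rows of
different conditions and corrupt the very patterns being compared.
Behavioral RDMs are cross-validated squared Euclidean distances with blocks
as partitions, so zero-leak simulations scatter around zero.

The confound regression fits per-subject neural distances on behavioral
distances by OLS with two-sided t-based p-values (statsmodels); a
significantly positive intercept with a flat slope is the signature of
neural information beyond subthreshold movements.  Degenerate behavioral
distances (zero variance) fall back to a one-sample t-test of the neural
distances.

## Synthetic-data conditions

The generators' defaults are the study conditions of the simulated
experiment.  Pattern variances `(a_plan, a_exec, s_plan, s_exec) =
(0.2, 2.0, 0.2, 1.0)`: execution carries a much stronger common pattern
than planning (the overall activation difference between moving and
planning), and the finger-specific planning variance is 20% of the
execution variance, mirroring planning/execution distance ratios in the
0.16–0.31 range.  Measurement noise at the run level defines a high-SNR
regime (σ² = 0.25, noise well below the execution signal; with 10 runs the
run-averaged noise attenuates naive correlations by only ~7%) and a
low-SNR regime (σ² = 2.0, attenuation factor
`√(s_p/(s_p+σ²/R)) · √(s_e/(s_e+σ²/R)) ≈ 0.65`, chosen so that noise bias
is clearly visible).  Ground-truth patterns are drawn as `G^(1/2) z` with
the symmetric square root, so the empirical second moment converges to G
and, at r = 1, matching-finger planning and execution residual patterns are
exactly proportional.

BOLD simulation is the forward model of the GLM: design matrix x true
betas plus Gaussian noise, i.i.d. across time and voxels by default, with
an optional SPD voxel covariance to exercise prewhitening.  No scanner
drift, motion or physiological noise is simulated.  Force noise (SD
0.02 N around a 0.3 N hold) is temporally smooth (10 ms Gaussian
autocorrelation), emulating slow physiological force fluctuations and
keeping the six 1 N press crossings of go trials exact; the preparatory
"leak" parameter shifts the cued finger by a constant during the delay and
is the only finger information in the traces.

Because the generators realize the analysis model's own assumptions
(Gaussian signal and noise, voxel exchangeability, white noise in time),
passing tests establish the correctness and calibration of the estimators
and inference machinery — not robustness to the artifacts of real 7T data
(autocorrelated and structured noise, motion residuals, non-Gaussian
signal), which remain the user's responsibility when applying the pipeline
to measurements.

## Problem sizes used in validation

The statistical validation suite runs at the paradigm's native scale where
that is cheap — 22 subjects, 10 runs, 6 conditions, 100-model grids, 200
voxels for correlation recovery; 1000 pure-noise datasets for unbiasedness;
2000 replicates for T² calibration; 200 sampled designs for VIF levels.
The behavioral confound simulation shortens each subject's session to 4
blocks of 12 trials (the full force pipeline still runs end to end) so that
100 replicates of 22 subjects stay affordable; the planted neural effect
size is d = 1, a clearly suprathreshold signal appropriate for testing the
detection logic rather than emulating a marginal empirical effect.
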