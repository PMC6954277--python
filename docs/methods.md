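# Methods

This note documents the models, numerical conventions and design choices
behind `rpnsig`, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Composite pain-sensitivity score

Heat (HPT) and cold (CPT) pain thresholds are means of repeated threshold
temperatures with the first repetition discarded as a test stimulus (the
protocol acquires 6 repetitions; the code accepts any count ≥ 2). The
mechanical pain threshold (MPT) is stored and scored on the log₁₀ mN scale —
the mean of log₁₀ forces over the ascending/descending staircase runs, which
equals the log of the geometric mean. T50, the temperature producing a
50/100 heat-pain rating, comes from a least-squares quadratic fit of rating
against temperature; the root at rating 50 is restricted to the stimulated
temperature range, and when both roots fall inside it the larger
(ascending-branch) root is taken, since ratings increase with temperature in
the painful range. A fit whose quadratic term is negligible is solved
linearly; a curve that never reaches the target rating raises an error
rather than extrapolating.

The composite score is the arithmetic mean of z-transformed thresholds with
HPT and MPT sign-inverted, so higher always means more pain-sensitive.
z-transformation uses *reference* statistics: a training cohort is scored
against its own population mean/SD, external cohorts against the training
cohort's, keeping all cohorts on one scale. The modality subset is
configurable (default all three) and the number used is recorded.
Extreme-value screening needs explicit normative 95 % bounds per modality;
the shipped template contains placeholders and the loader refuses to screen
until real values are supplied. A subject is excluded when at least two of
the three modalities fall outside their bounds.

## Motion quality control

Framewise displacement follows Power's convention: backward differences of
the six rigid-body parameters, rotations converted to arc length on a 50 mm
sphere, FD of the first frame defined as 0 so masks align with frames.
Frames with FD strictly above 0.15 mm are scrubbed (a literal reading of the
threshold: FD = 0.15 mm is retained); by default only the flagged frame is
dropped, with neighbour augmentation available behind a flag. Subjects are
excluded when mean FD (computed over *all* frames, pre-scrubbing) exceeds
0.15 mm or more than 30 % of frames are scrubbed; both reasons are reported
when both hold. Motion parameter files are read as six whitespace-delimited
columns, rotations (rad) before translations (mm), with an order override.

## Timeseries cleaning

The cleaning order is fixed: nuisance regression → bandpass → censoring.
Nuisance regression removes, per node, the OLS projection onto an intercept,
a linear trend, the Friston-24 motion block and (when noise signals are
provided) six CompCor components — the leading left-singular vectors of the
column-demeaned noise-region matrix, unit-normalised, signs fixed so each
component's largest-magnitude loading is positive. A rank-deficient design
degrades gracefully to the minimum-norm solution with a warning.

The bandpass (0.008–0.08 Hz) is an ideal discrete-Fourier filter: bins
inside the band are kept, everything else including DC is zeroed. This is
idempotent and has an exactly rectangular amplitude response, at the price
of ringing for signals with strong out-of-band power; a zero-phase
Butterworth alternative is exposed. Censoring after filtering follows the
reference order; the caveat that censored frames influence the filter output
of retained frames is inherent to that order. Filtering acts on regional
averages here, whereas an imaging pipeline filters voxels before averaging;
the two commute only approximately once masking varies, so this is a
documented approximation. Censoring refuses to proceed when fewer than 50
frames would remain.

## Connectome estimation

Partial correlations are computed from the precision matrix,
pcor_ij = −Θ_ij/√(Θ_ii Θ_jj), with the diagonal fixed to 0 and the global
grey-matter node last. The default covariance estimator is Ledoit–Wolf
shrinkage applied to per-node standardised signals — standardising first
makes the identity shrinkage target act on the correlation matrix, so the
estimate is invariant to per-node affine rescaling, as a correlation should
be. The plain empirical estimator is exposed for exact agreement with the
regression-residual definition of partial correlation (used as an
independent oracle in the tests) and refuses singular problems with advice
to use shrinkage. No Fisher z-transform is applied to the features. The
upper triangle in row-major order is the feature space, with
feature_index(i, j) = i(2n−i−1)/2 + (j−i−1); module-based reordering exists
for visualisation only and never affects feature indices.

## Predictive model

The pipeline is robust scaling ((x − median)/IQR with quantile range
(25, 75), unit scale where the IQR is 0), selection of the K features with
largest univariate |Pearson r| with the target (a ranking identical to the
regression F-statistic at fixed n; ties break to the smaller feature index),
and an elastic net with the 1/(2n) loss normalisation, so printed α values
are meaningful. The solver is scikit-learn's coordinate descent, but
optimality is certified independently by checking the subgradient (KKT)
conditions to 10⁻⁴, so tests never rely on the solver to validate itself.
Leave-one-subject-out grid search refits the whole pipeline in every fold;
the winning cell minimises LOO MSE with ties broken toward smaller K, larger
α and smaller L1 ratio (the sparsest, most regularised candidate).
Internal-validation metrics derive from the pooled LOO predictions at the
selected cell; because those folds also selected the hyperparameters, the
metrics are mildly optimistic, which is documented rather than corrected.

Explained variance is 1 − Var(y − ŷ)/Var(y) (0 for any constant predictor);
Pearson r is reported as NaN when either side is constant.

A fitted model exports a signature: the non-zero weights with their node
pairs, per-feature training median/IQR and the intercept (`full` mode).
Applying a full signature to new data reproduces the fitted pipeline's
predictions exactly. The packaged published signature is `weights_only` —
its scaler parameters and intercept were never published — so its scores are
defined up to an increasing affine map: valid for correlation-based
validation, not for absolute error metrics. Signature entries are matched to
input node orders by atlas index when available (two distinct published
region labels share atlas index 36, so label matching alone would be
ambiguous), falling back to labels.

## Permutation and bootstrap inference

Metric p-values permute the observed scores against fixed predictions
(external-validation style) with the add-one estimator
p = (1 + k)/(n_perm + 1), which is never 0 and never exceeds 1; "at least as
good" means lower MSE, higher explained variance, higher r. A full-refit
permutation mode for internal validation exists implicitly by rerunning the
CV on permuted labels, as the leak-check tests do. The bootstrap draws B
resamples of (subject, score) pairs with replacement (degenerate resamples
with constant scores are skipped), refits the full pipeline, and summarises
each connection *conditionally on having been K-best-selected in that
resample*: percentile 95 % CIs and two-sided sign p-values
2·min(#{w ≤ 0}, #{w ≥ 0})/#selected, floored at 1/#selected and capped at 1.
Selection frequencies over all B samples are always reported so
unconditional summaries can be derived. Confound association uses OLS R² as
the statistic (dummy-coded with first-level reference for categorical
covariates; ordinal covariates are treated as categorical), permuting the
covariate; missing values are dropped pairwise with n reported. No
multiple-testing correction is applied across confounds; any correction is
left to the user.

## Synthetic cohorts

Each subject carries a standard-normal latent trait s. Regional signals are
draws from a Gaussian graphical model: base precision = identity, with each
planted edge set to θ_e = −(0.25 + 0.15·s), i.e. a partial correlation of
about 0.25 at the population mean that strengthens by ~0.15 per trait SD.
Effects are planted on the precision scale so positive definiteness is
controllable (the diagonal is loaded to keep the minimum eigenvalue ≥ 0.05),
and the implied covariance is standardised to a correlation matrix so
marginal variances carry no trait information. A shared global fluctuation
is added to every region (weight 0.5) and observed with noise (SD 0.2) as
the global node — the fMRI picture of the global signal as a common
physiological/vigilance component. An earlier design that used the mean of
the region signals as the global node leaked trait information into all
region–global partial correlations (the planted covariance shifts the
variance of the mean) and was replaced. Frames are AR(1)-smoothed (φ = 0.3)
with the marginal covariance preserved.

QST thresholds load on the same trait with loading λ (default 0.8),
signed so higher s is more sensitive in every modality, using reference
statistics HPT 44.5 ± 1.5 °C, CPT 15 ± 7 °C, MPT 1.8 ± 0.35 log₁₀ mN —
healthy-adult forearm scale values. Latent thresholds are truncated to
physical bounds (HPT ∈ [33, 50.5] °C, CPT ∈ [0, 30] °C — thermal thresholds
cannot cross the 32 °C thermode baseline and stimulators cut off at
50.5/0 °C — and MPT within the 8–512 mN pinprick set), then expanded into 6
thermal repetitions (SD 0.3 °C) and 10 pinprick runs (SD 0.1 log₁₀ mN).
Motion is a random walk (0.01 mm / 2·10⁻⁴ rad per frame) with 0.5 mm
displacement spikes at probability 0.02 per frame, guaranteed to exceed the
scrubbing threshold. All randomness flows from one root seed through
per-subject substreams, so cohorts are bit-for-bit reproducible and
extensible without changing existing subjects.

The desk-scale default — 20 regions + global node, 200 frames at TR 2.5 s,
60 training and 40 external subjects, 4 planted edges — keeps every
experiment in the test suite at seconds-to-minutes scale while preserving
the structure of the real problem (regions + global node, TR, planted
sparse connectivity–trait coupling).

### Recovery experiments

The planted-structure recovery experiment estimates connectomes on the raw
generated signals rather than running the full cleaning chain: the
synthetic signals contain no motion coupling, drift or out-of-band noise,
so nuisance regression and the narrow bandpass would only discard
information (the 0.008–0.08 Hz band holds roughly a third of the effective
degrees of freedom of a white-ish signal), inflating estimation noise
without making the test more realistic. The end-to-end chain including
cleaning is exercised separately. Recovery fits use K = 10, ρ = 0.5,
α = 0.05: the four planted features are strongly mutually correlated (all
driven by the same trait), and a nearly pure L1 penalty at larger K tends to
keep one representative per correlated group, dropping a genuine edge in
favour of a proxy; a balanced L1/L2 mix with a tight univariate filter keeps
the whole planted set. Under these settings the planted edges land in the
top-10 weights in ≥ 85 % of replicate cohorts and the trained signature
attains r ≥ 0.4 on an independent cohort in ~100 %.

### What the synthetic tests show — and what they do not

Passing tests demonstrate that the implementation is internally correct
(oracle agreement, KKT optimality, calibrated permutation nulls, no CV
leakage) and that the pipeline can recover a known sparse
connectivity–trait structure at realistic desk-scale SNR. They do not
demonstrate real-data effect sizes: synthetic cohorts have Gaussian,
stationary signals, no scanner drift or physiological noise, no atlas
misregistration, and a single latent trait. External-validation metrics on
synthetic data (r ≈ 0.9) are therefore upper bounds of an idealised regime,
not forecasts for real cohorts.

## Numerical conventions and edge cases

* Elastic-net convergence tolerance 10⁻⁸ (solver), certificate threshold
  10⁻⁴; α = ∞-like values yield the intercept-only model with
  intercept = mean(y).
* Constant features receive unit robust scale and a zero univariate score;
  constant targets and constant covariates raise errors.
* Degenerate bootstrap resamples (constant y) are skipped; a feature never
  selected across resamples reports no CI/p rather than a fabricated one.
* The empirical covariance path raises on t ≤ n or a numerically singular
  covariance instead of silently inverting noise.
* Grid-search ties are broken deterministically (smaller K, larger α,
  smaller ρ) by cell iteration order.
* All add-one p-values lie in (0, 1].
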