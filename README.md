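# rpnsig

**A resting-state functional-connectome signature of pain sensitivity:
scoring, preprocessing, network estimation, sparse predictive modelling and
statistical validation.**

Individual sensitivity to pain is usually measured with quantitative sensory
testing (QST) — applying calibrated heat, cold and pinprick stimuli and
recording the thresholds at which they become painful. `rpnsig` implements
the full analysis chain that links such behavioural thresholds to
resting-state functional MRI connectivity, so that pain sensitivity can be
*predicted* from a few minutes of task-free brain imaging:

1. **QST scoring** (`rpnsig.qst`) — single-modality thresholds from raw
   trials (mean of repeated thermal thresholds after discarding the first
   test stimulus; log₁₀ geometric-mean pinprick force; T50 from a quadratic
   rating–temperature fit) and the composite pain-sensitivity score
   `score = mean(−z_HPT, +z_CPT, −z_MPT)`, z-scored against training-cohort
   reference statistics, with normative-bounds screening (subjects extreme
   in ≥ 2 of 3 modalities are excluded).
2. **Motion QC** (`rpnsig.motion`) — Power framewise displacement
   `FD_t = Σ|Δd| + 50 mm · Σ|Δθ|`, frame scrubbing at FD > 0.15 mm, the
   Friston-24 motion regressor expansion `[p, p², Δp, (Δp)²]`, and
   subject exclusion at mean FD > 0.15 mm or > 30 % scrubbed frames.
3. **Timeseries cleaning** (`rpnsig.preprocess`) — anatomical-CompCor
   principal components from noise-region signals, nuisance GLM
   (CompCor + Friston-24 + linear trend), an ideal Fourier bandpass
   retaining 0.008–0.08 Hz, then censoring.
4. **Connectome estimation** (`rpnsig.connectome`) — partial correlations
   `pcor_ij = −Θ_ij/√(Θ_ii Θ_jj)` from a (Ledoit–Wolf-shrunk) precision
   matrix over 122 atlas regions plus the global grey-matter signal as a
   123rd node; the 123×123 matrix's upper triangle is the
   P = 7503-dimensional feature space.
5. **Predictive modelling** (`rpnsig.model`) — a statsmodels-style
   `ConnectomePredictiveModel` whose `fit()` / `fit_loo()` return results
   objects for the pipeline *robust scaling → K-best univariate selection →
   elastic net* `(1/2n)‖y − b − Xw‖² + αρ‖w‖₁ + (α(1−ρ)/2)‖w‖₂²`, with
   leave-one-subject-out hyperparameter search over
   K ∈ {10, 15, …, 200}, ρ ∈ {0.1, …, 0.999}, α ∈ {0.001, …, 0.5},
   KKT-certified optimality, learning curves, and portable sparse
   signatures applied to new cohorts as a dot product.
6. **Inference** (`rpnsig.inference`) — permutation p-values for MSE /
   explained variance / Pearson r, bootstrap confidence intervals and
   selection-conditional sign p-values for every connection weight, and
   permutation-based R² confound tests.
7. **Synthetic cohorts** (`rpnsig.simulate`) — Gaussian graphical models
   with planted, trait-dependent edges, motion traces with displacement
   spikes, and QST trials loaded on the same latent trait, so the entire
   chain is testable end to end without any imaging data.

The package ships the published 21-connection resting-state pain-sensitivity
network (RPN) signature as a weights-only fixture
(`rpnsig.load_rpn_signature()`), including its strongest connection
(parietal operculum/posterior STG – posterior putamen, weight 0.270) and the
global grey-matter node's single incident weight (−0.086).

## Worked example

Train on a synthetic 60-subject cohort with four planted connectivity–trait
edges and validate on an independent 40-subject cohort:

```python
from rpnsig import (SyntheticConfig, generate_cohort, prepare_cohort,
                    ConnectomePredictiveModel, PipelineHyperparams)

train = prepare_cohort(generate_cohort(SyntheticConfig(n_subjects=60, seed=1)),
                       clean=False)
test = prepare_cohort(generate_cohort(SyntheticConfig(n_subjects=40, seed=2)),
                      reference=train.reference, clean=False)

model = ConnectomePredictiveModel(train.X, train.y, node_labels=train.node_labels)
res = model.fit(PipelineHyperparams(k_best=10, l1_ratio=0.5, alpha=0.05))
print(res.summary())
ext = res.evaluate(test.X, test.y, n_perm=1000, seed=0)
print(ext.metrics)
```

prints

```
Connectome predictive model — elastic net on K-best partial correlations
==========================================================================
subjects:    60    features: 210
K-best: 10    l1_ratio: 0.5    alpha: 0.05
non-zero weights: 7    intercept: -0.1174
KKT violation: 1.79e-09
--------------------------------------------------------------------------
connection                                  weight
region_001 – region_002                     0.2997
region_007 – region_008                     0.2673
region_005 – region_014                    -0.2617
region_005 – region_006                     0.1986
region_003 – region_004                     0.1914
region_007 – mean GM                       -0.0286
region_012 – region_016                    -0.0143
{'mse': 0.224, 'mae': 0.396, 'explained_variance': 0.777, 'pearson_r': 0.903}
```

All four planted edges (region pairs 1–2, 3–4, 5–6, 7–8) carry the largest
positive weights; the remaining small entries are noise. On the held-out
cohort the signature explains ~78 % of the variance in the composite
pain-sensitivity score (r = 0.90, permutation p = 0.001 at 1000
permutations) — synthetic cohorts are far cleaner than real fMRI, so these
figures characterise the pipeline, not the real-data effect size.

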