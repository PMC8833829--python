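# Methods

`tnbcpet` re-implements, on synthetic data, a baseline [18F]FDG PET/CT
prognostic analysis for early triple-negative breast cancer (TNBC): fixed
SUV-threshold tumor segmentation, extraction of metabolic, volumetric and
textural features, scanner-batch diagnostics and harmonization, and survival
modelling with threshold discovery. This note records the models, the
defaults and why, the numerical choices, and what the synthetic data do and
do not establish.

## SUV and segmentation

Activity concentration c (Bq/mL) is converted to the body-weight standardized
uptake value

    SUV = (c / rho) / (A_inj / W),

with tissue density rho fixed at 1 g/mL (the universal PET convention that
maps Bq/mL to Bq/g), injected activity A_inj in Bq and body weight W in g.
No decay correction is applied; volumes are assumed decay-corrected upstream.

The tumor VOI is `{SUV >= 2.5}` inside a user-supplied axis-aligned ROI box,
split into 26-connected components. The threshold is inclusive: the study
design excludes tumors with SUVmax *below* 2.5, so a voxel at exactly 2.5
belongs to the VOI. 26-connectivity is the natural choice for blob-like PET
lesions. Components are ranked by SUVmax (ties: larger component, then lower
label); the top-ranked component is the index lesion used for texture
analysis.

## Features

Per tumor, eleven quantities: SUVmax, SUVmean, SUVpeak, MTV, TLG, and six
texture features.

* **SUVpeak** — mean over all voxels (inside the grid, masked or not) whose
  centers lie within a 1 cm^3 sphere (radius 6.2035 mm) centered on the
  hottest VOI voxel. A sphere, not a cube, and including out-of-mask voxels,
  per the EANM peak convention.
* **MTV** — voxel count x voxel volume, cm^3. **TLG** = SUVmean x MTV; the
  identity is exact by construction and asserted at 1e-9 relative tolerance
  on every extraction.
* **Discretization** — absolute bounds 0–20 SUV, 64 levels (bin width
  0.3125 SUV), `level = 1 + floor(SUV / 0.3125)` with values >= 20 clipped to
  level 64. Fixed absolute bounds make texture values comparable across
  tumors regardless of their individual SUV range.
* **GLCM** — one pooled symmetric co-occurrence matrix over the 13 unique
  3-D unit directions (both voxels inside the VOI), normalized to sum 1.
  Homogeneity = sum C(i,j)/(1+|i-j|); entropy = -sum C log2 C, in **bits**.
  Pooling into a single matrix (rather than averaging per-direction
  features) follows the single-matrix convention of the texture-index
  literature this analysis style derives from.
* **GLRLM** — maximal equal-level runs along the same 13 directions pooled
  into one matrix; SRE and LRE are the inverse- and square-length-weighted
  means.
* **GLSZM** — 26-connected equal-level zones; LGZE and HGZE are the inverse-
  and square-level-weighted means over zones.
* VOIs with fewer than 8 voxels give degenerate matrices; texture values are
  set to NaN with a warning.
* **Multifocal tumors** — MTV and TLG sum over lesions; SUVmean is the
  MTV-weighted mean, the one weighting that preserves TLG = SUVmean x MTV
  after aggregation; SUVmax, SUVpeak and textures come from the index
  lesion.

All three texture matrices are verified against brute-force oracles
(pair enumeration, full line scans, flood fill) on batches of random
discretized VOIs.

## Harmonization and gPCA

Feature tables (rows = patients, a scanner batch label, numeric features)
can be harmonized three ways:

* **standardize** — within-batch z-score, re-anchored to the pooled mean/SD;
* **RBE** — subtract least-squares batch-mean offsets (reference = first
  batch in row order); idempotent;
* **ComBat** — parametric empirical Bayes: features standardized against the
  batch-mean model, per-batch location/scale estimates shrunk toward
  normal / inverse-gamma moment-matched priors using direct (non-iterative)
  conditional posterior means, then back-transformed. Variances use the n
  (ddof = 0) denominator throughout, which makes two literally identical
  batches pass through bit-near-exactly (gamma_hat = 0 and delta2_hat = 1
  hold analytically); when the across-feature spread of the scale estimates
  is ~0 the inverse-gamma prior is degenerate and variance shrinkage is
  skipped. Requires >= 2 rows per batch; missing values are an error
  (nothing is imputed).

**Guided PCA** quantifies a batch effect: with X the feature-centered data
and Y the one-hot batch matrix, delta = var(X v) / var(first PC of X), where
v is the first right singular vector of Y'X. delta is in [0, 1] by the
Rayleigh-quotient bound. Significance comes from random batch-label
permutations with the add-one estimator p = (1 + #{delta_perm >=
delta_obs}) / (1 + B), so p is in (0, 1] and reproducible bit-for-bit for a
fixed seed. Note delta is not small under the null when features share a
dominant variance direction — the permutation p, not delta itself, carries
the evidence.

## Survival analysis

Endpoints are right-censored months from diagnosis (DFS to relapse, OS to
death). Kaplan–Meier estimation, log-rank tests and Cox models are computed
with `lifelines`; ties use the Efron correction (lower bias with tied event
times; the handling was an open choice). Medians that are never reached are
reported as a distinguished `None`, never a number. Backward selection
starts from the full model of univariately significant covariates
(two-sided p < 0.05, no multiplicity adjustment) and drops, at each step,
the covariate whose removal lowers AIC most; the covariate-free model's AIC
is computed from the closed-form Efron null partial likelihood. Note that
AIC retains a pure-noise covariate whenever its likelihood-ratio statistic
exceeds 2 — about 15.7% of the time under the null — so "noise usually
dropped" means ~84%, not ~100%.

Prognostic thresholds use a fixed 24-month horizon ROC: subjects with an
event at or before the horizon are positives; subjects event-free with
follow-up reaching it are negatives; subjects censored earlier are excluded
(a standard fixed-horizon rule; a time-dependent ROC would use them, which
is a documented limitation). Cutoffs predict positive at feature >= cutoff;
Youden's J = sens + spec - 1 picks the operating point, ties resolved to the
lower cutoff. Groups dichotomized at the chosen cutoff are compared by
Kaplan–Meier and log-rank.

In the full pipeline the log-transformed modelling table can contain
log TLG = log SUVmean + log MTV exactly; before the multivariate fit the
candidate list is pruned greedily to a full-rank subset (dropped names are
recorded in the manifest).

## Synthetic data

* **Lesion volumes** — an ellipsoid painted on a 0.5-SUV background with one
  of four intensity models (uniform; voxel-wise Gaussian noise; a hot
  concentric core of chosen volume fraction; a center-to-rim linear
  gradient), then optionally blurred with an isotropic Gaussian PSF standing
  in for scanner resolution (default 6 mm FWHM in the pipeline, 3 mm
  voxels). Ground truth (mask, MTV, SUV statistics) is taken pre-blur.
* **NEMA IQ phantom** — six spheres of 10/13/17/22/28/37 mm inner diameter
  on a 57.2 mm ring, filled at 5:1 sphere-to-background. With no PSF the
  measured contrast is exactly 5:1; with a 6 mm PSF the SUVmax recovery
  coefficient rises monotonically with sphere size, the expected
  partial-volume behavior.
* **Cohorts** — relapse times follow an exponential proportional-hazards
  model on centered (log MTV, log TLG, entropy, N+PET) with default log-HRs
  (log 1.4, 0, log 2.0, log 2.9) echoing the per-unit effect sizes such
  analyses report; the baseline rate (0.0065/month) and uniform 12–84 month
  censoring (staggered accrual, administrative horizon 84 months) were
  chosen once to yield roughly 30% observed relapses. Death occurs only
  after relapse, delayed by an exponential residual (mean 12 months), so
  DFS <= OS holds by construction. Relapse types are drawn with the
  23/9/1/1 metastatic/locoregional/contralateral/second-cancer mix.
* **Screening-flow fixture** — 679 deterministic records arranged so the
  eligibility cascade excludes exactly 245 (receptor-positive), 277 (prior
  cancer), 30 (metastatic), 13 (pre-PET surgery) and 3 (SUVmax < 2.5) under
  first-reason attribution, leaving 111 enrolled with the tabulated clinical
  mix (50 N+PET, 80 T1–T2, 103 grade 3, 12 inflammatory, 25 multifocal) and
  outcomes (34 relapses, 20 deaths).

What the synthetic data do **not** emulate: reconstruction/sinogram physics,
scanner-specific noise texture, respiratory motion, lymph-node foci (N+PET
is an input flag), or any real correlation structure between histology and
imaging beyond the single latent severity score. Passing tests therefore
establish the correctness and calibration of the computations, not clinical
performance on real cohorts.

## Problem sizes and determinism

The pipeline default is 111 patients (image-based extraction takes a few
seconds at 3 mm voxels); simulation-based checks use 100–200 replicates at
n = 100–1000, sizes at which the asserted recovery bands and calibration
rates are comfortably stable. Every stochastic component takes an explicit
seed (NumPy `default_rng`); reruns with the same seed are byte-identical in
all CSV outputs.

## Known limitations

* Entropy's log base in vendor radiomics software varies; bits are used
  here, so absolute entropy values are not comparable to tools using
  natural logs.
* Only parametric ComBat is implemented; no covariates are protected during
  harmonization.
* The horizon ROC discards early-censored subjects rather than weighting
  them (no inverse-probability-of-censoring correction).
* The eligibility predicate consumes pre-coded receptor/flag columns; it
  does not interpret IHC readings.
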