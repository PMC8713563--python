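# Methods

This note documents the models, parameter choices and numerical decisions
behind `icdpipe`, and what the synthetic-cohort experiments do and do not
demonstrate about real data.

## Exposure scoring and quality control

Trauma exposure is the unweighted sum of nine binary screen items, capped at 3
(`te_coded`), because subjects with three or more events are pooled for
regression stability. QC removes participants in a fixed order — mean motion
per TR > 0.3 mm, censor fraction > 30%, failed coregistration (an optional
input flag, never computed), serious brain injury, missing trauma items,
missing maternal education — recording only the first reason triggered, so
per-reason counts are disjoint. Both motion rules are strict inequalities:
values exactly at 0.3 mm or 30% pass. "Mean motion per TR" is the mean
framewise displacement over translation parameters; a configurable option
converts rotations to arc length at a 50 mm radius and adds them in
quadrature.

## Preprocessing

Stages run in a fixed order: drop the first four frames → censor frames →
6 mm FWHM Gaussian smoothing → motion/band-limit nuisance GLM → tissue-based
regression. Frames are censored when the frame-to-frame translation jump
exceeds 0.3 mm (strictly) or when more than 10% of voxels deviate from their
temporal median by over 3 robust (MAD-based) SDs; the outlier rule censors
essentially nothing on clean Gaussian data. Censored frames are excluded from
every subsequent fit and zeroed in outputs.

Band limiting to 0.01–0.08 Hz is done **inside** the GLM by regressing out
sine/cosine pairs for every frequency outside the band, evaluated at retained
frame times — exact under censoring, where FFT filtering is not. Below the
band the frequency grid runs in half-bin steps because slow drifts rarely sit
on a DFT bin; with integer bins only, an off-bin 0.005 Hz drift retains ~17%
of its amplitude, with the half-bin grid under 2%, while in-band signal keeps
≥ 97%. The design totals ~88 columns for a 120-frame run (intercept, 6 motion
parameters, 6 derivatives, out-of-band pairs), leaving ~28 residual degrees of
freedom at typical censoring. A subject whose censoring leaves fewer than 15
residual df is flagged and excluded: below that, voxel residuals collapse
toward a low-rank subspace and every pairwise correlation tends to ±1 — a
20%-censored subject showed exactly this failure before the guard existed.

Tissue regression erodes the white-matter and ventricle masks by one voxel
(6-connected, single pass; empty erosion falls back to the uneroded mask with
a warning), then removes the eroded-WM mean and the first three principal
components of the eroded-ventricle voxel×time matrix from every voxel.
Smoothing is mask-renormalized (normalized convolution), so constants are
preserved and nothing bleeds across a mask boundary.

## The intrinsic connectivity distribution

Per voxel, Pearson correlations to all other gray-matter voxels are computed
over retained frames; negatives are discarded; the empirical survival on
τ ∈ {0.01, …, 0.99} is fit with S(τ) = exp(−(ατ)^β) by least squares in
log-parameter space (positivity by construction), starting from the exact
log-log linearization log(−log S) = β log α + β log τ and falling back to a
small restart lattice (α ∈ {0.5, 1, 2, 4} × β ∈ {0.5, 1, 2}) on
non-convergence. A brute-force (α, β) lattice is used in tests as an
independent check that the fit reaches the global optimum; recovery of
in-family curves is exact to ~1e−16 relative error. Curves with fewer than
five interior points (survival strictly inside (0,1)) carry no decay
information and are marked failed — this includes voxels so strongly coupled
that their survival stays at 1 through τ = 0.99. Failures propagate as NaN,
never as silent zeros, and a subject aborts if over 20% of voxels fail.
Voxels are independent, so results are bit-identical for any chunk size. The
model form is pluggable (`icd_model`); α comparisons across voxels are most
interpretable between curves of similar shape (similar β), and the package's
directionality convention — smaller α ⇔ higher connectivity — is validated by
stochastic-dominance experiments.

## Voxel-wise regression and cluster correction

The per-voxel OLS uses six terms (intercept, TE, sex, sex×TE, age, maternal
education), female = 0 coding, so the interaction coefficient is the
male−female slope difference and per-sex slopes are recoverable by addition.
Cluster correction is nonparametric: supra-threshold voxels (two-sided
p < 0.001) form 6-connected components (18/26 configurable), and the null of
the **maximum component size** is built by Freedman–Lane permutation — permute
reduced-model residuals, refit the full model, re-threshold — with corrected
p = (1 + #{null ≥ size}) / (n_perm + 1). The permutation loop exploits the
identity that the reduced-model fit lies in the full design's column space, so
each draw costs one (k×n)(n×V) product. The parametric/ACF-based correction
used with AFNI-style pipelines is deliberately replaced by this
assumption-light null; method and n_perm (default 1000) are recorded in
output metadata.

Under a global null of 4 mm-smoothed noise maps on the full 20×20×12 grid
(200 datasets, n = 100, 500 permutations) the measured family-wise
false-positive rate is ≈ 0.015–0.045 — inside the binomial 95% band around
the nominal 0.05, with the shortfall caused by the discreteness of cluster
sizes at desk scale. With unsmoothed (spatially independent) maps the test is
far more conservative, since suprathreshold voxels are isolated; cluster-extent
inference presumes smooth fields.

Peak voxels are the in-cluster maximum |coefficient| (ties: smallest linear
index), reported in mm via the affine; hemisphere comes from the peak's
position relative to the grid midline.

## Seed-based networks and overlap

A cluster's mean time series is correlated with every gray-matter voxel and
Fisher-z transformed (|r| clipped at 1−1e−7). A two-sided one-sample t-test
across subjects with Benjamini–Hochberg FDR defines the network as voxels
passing both thresholds, restricted by default to positive mean z. The
published-cohort thresholds (p < 1e−44, FDR < 3e−16) are kept as library
defaults but presume n ≈ 900; desk-scale runs use p < 1e−6, FDR < 1e−4.
Overlap profiles report the percentage of network voxels in each of the seven
reference labels plus unlabeled; they sum to 100 by construction and are
validated on every input. Pairwise overlap between constructed networks is
directional: |A∩B| / |B| × 100, the share of B inside A.

## The synthetic cohort

Real BOLD data is unavailable without controlled access, so every experiment
runs on a generated cohort whose correlation structure is controlled exactly —
the quantity both ICD and seed connectivity are functions of.

**Geometry.** A 20×20×12 grid at 3 mm isotropic, with a diagonal affine.
Gray matter is three 100-voxel blocks: a somatomotor-like community
(parcellation label 2), a DMN-like community (label 7) and weakly coupled
background gray matter striped with the remaining labels; a 100-voxel WM slab
and a 100-voxel ventricle block supply nuisance sources.

**Signals.** Within a community, series follow a single-factor model
x = √ρ·f + √(1−ρ)·η with unit-variance band-limited (0.01–0.08 Hz) latent
signals, so the within-community signal correlation equals ρ exactly and the
covariance is positive semi-definite for any ρ ∈ [0,1) (equicorrelation;
verified before sampling, values clipped to [0, 0.95] with a logged warning).
White observation noise (SD 0.3), a slow 0.005 Hz drift, and WM/ventricle
sources mixed into gray matter at 0.3 of signal SD give the preprocessing
stages real work; removing them measurably improves coupling estimates.
Motion is a random walk (0.02 mm steps) with displacement spikes
(per-frame probability 0.04, magnitude ≥ 0.35 mm) yielding ~8% censored
frames — matching the motivating study's average post-QC scan loss — and 15%
of subjects receive inflated motion so QC has realistic work; 12% carry an
injury flag and ~1% missing fields.

**Covariates.** Age is truncated-normal 14.6 ± 3.3 on [8, 21]; sex is
Bernoulli(0.578 female); the nine trauma items follow a one-factor Gaussian
copula with tetrachoric correlation 0.4 — adverse events co-occur, which is
also what creates the multi-event tail that motivates capping at 3 — with the
common marginal rate calibrated by quadrature so P(≥1 event) = 0.478;
maternal education decreases with raw event count (−0.8 y per event, noise
SD 2 y, clipped to [6, 20]).

**Planted effects and their size.** Somatomotor coupling is
0.68 − 0.21·TE (all subjects); DMN coupling is 0.55 + 0.06·TE in males and
0.55 − 0.06·TE in females. The main-effect slope is large by design, set by a
power analysis of the desk-scale conditions: with a ~6 min scan the
subject-level α noise is ~0.4 (finite-scan correlation sampling, shared
across a community, ~28 residual df), α responds to coupling at only ≈ −2 per
unit correlation (steeper below ρ ≈ 0.45, flat above ρ ≈ 0.6 where 6 mm input
smoothing pushes correlations toward the survival-grid ceiling), and the
sex×TE column inflates the TE coefficient's SE ≈ 1.6×. At ~45 analyzable
subjects these facts put the voxel-wise detection threshold near a coupling
slope of 0.2 per TE unit; the planted slope spans most of the usable coupling
range as a result. Even so, detection at n = 60 is probabilistic (roughly
four runs in five; one tested seed fails because its few TE=3 subjects make
the TE and interaction columns nearly collinear). The ±0.06 sex-specific
slopes are deliberately **below** the n = 60 detection floor — the
interaction machinery is instead validated by direct parameter-recovery
experiments at n = 300, where 95% CI coverage for both sex slopes lands in
[90%, 99%].

**Determinism.** Every draw flows from named seeds: covariates and each
subject's image use separate child streams keyed by seed and subject index,
so any subject regenerates bit-identically in isolation, and two identically
seeded end-to-end runs produce byte-identical statistical tables.

**What passing these experiments does not show.** The generator has no
scanner physics, no slice timing or registration error, no anatomical
variability, no physiological (cardiac/respiratory) structure, and its
communities are spatially compact blocks with exactly equicorrelated signals.
Passing the suite demonstrates that the estimators recover the quantities
they target under the model the analysis assumes — not that the pipeline's
assumptions hold in acquired fMRI.

## Problem sizes

Validation experiments default to: 100 survival curves for recovery, 100
dominance pairs, 100 single-subject simulations for the connectivity
ordering, 1000 OLS oracle instances, 100 replicates at n = 300 for
interaction coverage, 200 global-null datasets (n = 100, 500 permutations)
for calibration, 10 planted-cluster datasets at n = 300, one 50-subject
cohort for seed-network recovery, and two 60-subject demo runs for the
determinism check. The demo uses 500 permutations; the library default is
1000.
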