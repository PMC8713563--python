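# icdpipe

Voxel-wise **intrinsic connectivity distribution (ICD)** analysis of
resting-state fMRI, built to study how childhood trauma exposure relates to
functional connectivity in youth — and how that relationship differs by sex.

The package implements the full analysis chain on already-registered volumes:
trauma-questionnaire scoring and participant QC, fMRI preprocessing, voxel-wise
ICD estimation, a voxel-wise interaction regression with permutation
cluster-extent correction, and seed-based network definition scored against a
7-network reference parcellation. Because the motivating study's cohort is
controlled-access, the package ships a first-class **synthetic cohort
generator** with planted exposure-connectivity effects, so the entire chain is
testable end to end on any machine.

## The statistic at the core

For a gray-matter voxel *v*, let *r₁ … r_N* be its Pearson correlations with
every other gray-matter voxel (negatives discarded). The empirical survival
function

&nbsp;&nbsp;&nbsp;&nbsp;*Ŝ_v(τ) = #{rᵢ > τ} / N*, on the grid τ ∈ {0.01, …, 0.99}

is fit by nonlinear least squares with the stretched-exponential model

&nbsp;&nbsp;&nbsp;&nbsp;*S(τ) = exp(−(ατ)^β)*,&nbsp;&nbsp; α, β > 0.

α is an inverse scale: a voxel with many strong connections has a slowly
decaying survival curve, hence a **small α (low α = high connectivity)**;
β controls the decay shape. This summarizes a voxel's whole connectivity
distribution without choosing a correlation threshold.

Per subject the α (and β) maps are smoothed (4 mm FWHM) and entered into a
voxel-wise OLS model

&nbsp;&nbsp;&nbsp;&nbsp;α_v = b₀ + b₁·TE + b₂·sex + b₃·(sex×TE) + b₄·age + b₅·maternal education + ε

with trauma exposure TE coded 0–3 (nine binary items, unweighted sum capped
at 3) and sex coded female = 0 / male = 1, so b₁ is the female TE slope and b₃
the male−female slope difference. Voxels with two-sided p < 0.001 on a term
are grouped into 6-connected components, and component size is referred to a
Freedman–Lane permutation null of the maximum cluster size (cluster α = 0.05).
Significant clusters seed group connectivity networks (seed-mean correlation →
Fisher z → one-sample t-test with joint p/FDR thresholds), which are scored by
the percentage of their voxels in each label of a 7-network parcellation.

## Worked example

The numbered scripts under `analysis/` run the full chain on the default
synthetic cohort (60 subjects, 20×20×12 grid at 3 mm, TR 3 s, 124 frames;
somatomotor-like coupling falls by 0.21 per TE unit for everyone, DMN-like
coupling moves ±0.06 per TE unit with opposite signs by sex):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py
python analysis/03_fit_icd.py
python analysis/04_voxel_glm.py
python analysis/05_networks_overlap.py
```

which prints (abridged):

```
included 46 / 60 subjects
  excluded   8  brain_injury
  excluded   5  motion
  excluded   1  censor_fraction
  mean alpha, somatomotor-like: 1.257
  mean alpha, DMN-like        : 0.977
  mean alpha, background      : 1.898
te: 1 significant cluster(s) (voxel |t| > 3.55, null 95% size 1)
  cluster 1: 100 voxels, peak (6.0, 18.0, 12.0) mm (left), avg effect +0.523, corrected p 0.001996
te: network of 100 voxels; best reference label 2 at 100.0% (unlabeled 0.0%)
```

Reading this: QC removed 14 of 60 simulated participants (injury, motion,
censoring); the coupled communities show lower mean α than background gray
matter, i.e. higher connectivity; the TE regression recovers the planted
somatomotor community as one 100-voxel cluster whose **positive** coefficient
(+0.52 α per TE unit) says connectivity *falls* as exposure rises; and the
network seeded from that cluster lies entirely inside the somatomotor
reference label. The sex×TE slopes (±0.06) are intentionally below the
detection floor at this sample size; recovering them needs n ≈ 300 (see
`docs/methods.md`).

The same pipeline is available as one command:

```bash
icdpipe demo --seed 1 --out results/demo
```

and the individual stages (`simulate`, `qc`, `preprocess`, `icd`, `glm`,
`network`) operate on NIfTI/TSV files for use outside the simulation.

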