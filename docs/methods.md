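# Methods

This note documents the models, defaults, and design decisions behind
`wsdlprog`: what is simulated, what is fitted, how the pieces are wired, and
what the packaged experiments do and do not demonstrate.

## Synthetic cohorts (`synthetic_cohort`)

The generator emulates the statistical structure of a single-centre
PET/CT prognosis study, not its physics.

**Scanner profiles.** Three built-in presets fix the voxel grid and an
effective reconstruction profile applied as Gaussian blur plus additive
noise: `scanner1` (5.47 mm isotropic, 6 mm FWHM, σ = 0.50 SUV), `scanner2`
(2.7 × 2.7 × 2.79 mm, 4 mm, σ = 0.35) and `scanner3` (1.6 × 1.6 × 1.5 mm,
3 mm, σ = 0.45). The blur FWHM of `scanner1` matches its stated
reconstruction filter; the other two FWHM/noise values are plausible
choices for a regularized and an unfiltered TOF reconstruction. No
sinograms, attenuation or reconstruction algorithms are modelled.

**Lesions.** One axis-aligned ellipsoid per patient, radii log-normal
(median 11 mm, per-axis log-sd 0.11), mean SUV log-normal (median 6,
log-sd 0.3), with a multiplicative log-Gaussian texture field
(correlation length ≈ 6 mm, sd ≈ 0.15) inside the lesion. The
relapse-prone class is shifted upward by `effect_size` standard deviations
in log mean-SUV and log radius and gets texture variance larger by
0.10 × `effect_size`; `effect_size` is therefore a Cohen's-d-like
separation, with 0 collapsing the two classes onto one distribution. The
default 1.0 is a moderate, partially overlapping regime. The CT channel is
a smooth background with additive soft-tissue contrast at the lesion. The
binary mask is the pre-blur ellipsoid, i.e. segmentation is treated as
ground truth. Grid default 48³ voxels.

**Survival.** PFS is exponential with class hazards 0.050/month
(relapse-prone; ≈ 30% two-year PFS) and 0.0044/month (non-relapse; ≈ 90%),
chosen to match the order of the two-year PFS split the PSI groups are
expected to show. Labeled patients' administrative follow-up is
24 + Exp(18) months; unlabeled follow-up is Uniform(3, 24) months and
their outcome fields are never populated — nothing downstream can read the
latent class or event status of an unlabeled patient (the `Cohort.truth`
map exists only for oracle experiments and evaluation).

For labeled patients the relapse *label* is defined as the latent class,
and the survival draw is repeated until the observed-event status agrees
with it (an event within follow-up for relapse, none for non-relapse).
This keeps the configured prevalence exact, guarantees the "event or ≥ 24
months event-free" contract, and preserves the class-conditional hazard
shapes; `simulate_survival` itself remains unconditional and is used as-is
for the unlabeled pool. Default prevalence 23/84 ≈ 0.274 (the value implied
by the assumed study's sensitivity denominators); the split is stratified
per class with largest-remainder rounding, as is the 39/29/15 scanner
assignment of the unlabeled pool.

**Covariates.** Age, gender, LDH, ECOG, EBV-DNA, β2-microglobulin,
Ann Arbor stage and B symptoms are drawn from uniform/binomial/log-normal
families with class-dependent shifts scaled by `covariate_assoc`, so a
multivariate Cox stage has non-zero but modest clinical signal.

**What passing tests show.** The generator produces exactly the
separations and marginals it is configured with; success of the pipeline
on these cohorts demonstrates the *mechanism* (implicit labels recover
usable information from an unlabeled pool whose phenotype is genuinely
class-linked), not clinical performance. Real PET data differ in lesion
shape, multifocality, segmentation noise, scanner batch effects beyond
blur/noise, and non-exponential hazards.

## ROI preparation and PET metrics (`pet_io`)

Volumes are NIfTI with the spacing encoded in a diagonal affine; masks are
binarized at 0.5 on read. The network input is a cube of physical side
96 mm centred on the mask centroid, trilinearly resampled to 32³ voxels
(both configurable); 96 mm covers the simulated lesions on all three
grids. The PET channel stays in SUV units and is z-scored with the pooled
in-mask mean/SD of the labeled *training* volumes, frozen and reused for
test and unlabeled patients (no test-time leakage); the CT channel is
min–max scaled to [0, 1] per crop. Sample points outside the source grid
take the per-channel background value, which is exactly 0 after PET
normalization. Voxel indices are 0-based and crop windows half-open.

SUVmax is the mask maximum; the metabolic volume is the set of mask voxels
with SUV ≥ 41% of SUVmax (a common harmonization convention — the
delineation rule is configurable because no single standard exists);
SUVmean averages over that volume and TLG = SUVmean × MTV.

## The network (`dcnn`)

An 18-layer-style residual topology moved to 3D and narrowed: stem 3³
convolution (stride 2) → four stages of basic blocks (two 3³ convolutions
with batch normalization, identity or 1³-projection shortcuts), each stage
downsampling ×2, widths (16, 32, 64, 128) → global average pooling →
dropout (default off) → fully connected 2-way softmax. The last width is
required to be 128 so the pooled vector is exactly the 128-feature deep
descriptor; the narrow widths are the natural counterpart of the classic
(64, 128, 256, 512) under that constraint. The head is zero-initialized,
so an untrained network outputs p_pos = p_neg = 0.5 for every input.

The implementation is plain NumPy (channels-last float32, convolutions as
per-tap matrix products, analytic backward passes, Adam). Single-threaded
runs are bit-for-bit reproducible given the config seed, which drives
initialization, the validation split, shuffling and augmentation.

Training minimizes weighted cross-entropy (per-class inverse-frequency
weights folded in by default), batch size 8, learning rate 1e-3, up to 60
epochs with early stopping (patience 10) on a stratified 20% validation
split of the training patients; the best-validation-loss checkpoint is
restored. Optional augmentation (axial flips, ±5-voxel shifts) is off by
default so reproducibility tests are exact. Sets too small for a
two-class validation split simply train to the epoch budget.

`desk_scale_config` is the configuration the packaged cohort experiments
use: widths (8, 16, 32, 128), one block per stage, batch 16, learning rate
3e-3, 12 epochs, patience 4 — a full 10-seed WSDL-vs-CDL comparison on
default cohorts (32³ inputs) then runs in about six minutes on one CPU.

## PNU classification (`pnu_classifier`)

Risk estimators over linear scores s(x) = w·x + b with loss ℓ (logistic by
default; squared available for cross-checks), class prior π_p:

- R̂_PN = π_p · mean ℓ(s) over positives + (1−π_p) · mean ℓ(−s) over negatives
- R̂_PU = π_p · mean ℓ(s) over positives + [mean ℓ(−s) over unlabeled −
  π_p · mean ℓ(−s) over positives]
- R̂_NU mirrors R̂_PU with the negative class kept and the positive class
  estimated from the unlabeled pool.

The bracketed terms are unbiased for the missing-class risk; with the
non-negative correction (default on) they are clamped at 0, which
stabilizes small samples at the cost of bias. γ ∈ [−1, 1] interpolates
between PN, PU and NU as in the README; γ = 0, 1, −1 reproduce the pure
estimators exactly.

Fitting is deterministic full-batch gradient descent from (w, b) = 0,
step 0.1 halved on any risk increase, at most 2000 iterations,
convergence at relative risk change < 1e-8; the clamp takes subgradient 0
on its flat side. L2 penalty 1e-3 by default. γ is chosen from the grid
(−0.5, −0.25, 0, 0.25, 0.5, 0.75, 1) by 5-fold cross-validated PN risk on
the labeled data (the unlabeled pool joins every training fold); nothing
in the available description fixes the authors' selection rule, so this
pragmatic rule is a package choice. π_p defaults to the labeled-training
relapse prevalence — the standard PNU prior assumption; prior
misspecification can be probed via `CohortConfig.unlabeled_prevalence`.

Implicit labels are the sign of the fitted score (ties negative), with
confidence |score| through the logistic link. "Implicitly derived ...
leading to maximized prediction probability" is ambiguous between risk
minimization and probability maximization; this package implements risk
minimization.

## Pipeline and PSI (`wsdl_pipeline`)

Step 4 retrains from fresh initialization rather than fine-tuning (a
`fine_tune` flag provides the alternative); one labeling round only, no
iterative self-training. Unlabeled sample weight defaults to 1.0, with
optional confidence weighting. Zero-weight samples are dropped before
training and CDL shares the step-4 training seed, so `unlabeled_weight=0`
reproduces the CDL network bit-for-bit — a useful degeneracy check.

PSI = p_pos / max(p_neg, 1e-12). PSI exactly 1 is assigned to the low
group (the dichotomy is stated as strict "> 1" / "< 1" with no tie rule;
with normalized probabilities the boundary case is exactly p_pos = 0.5).
Every run returns a manifest whose SHA-256 checksum covers mode, cohort
and module configs and seeds; identical manifests reproduce identical PSI
tables.

## Survival statistics (`survival_stats`)

Kaplan–Meier, log-rank and Cox (Efron tie handling, Wald inference) are
delegated to lifelines; Fisher's exact test to scipy. The time-dependent
ROC is implemented in-package — cumulative cases / dynamic controls at
t = 24 months by default, cases weighted by 1/G(T⁻) and controls by
1/G(t) with G the Kaplan–Meier estimator of the censoring distribution,
ties counted ½ — because per-threshold ROC coordinates are needed
alongside the AUC; it is cross-checked against scikit-survival's
cumulative/dynamic AUC in the tests. Significance is read at 0.05 and the
univariate screen applies no multiplicity correction, matching the
evaluation protocol it mirrors; continuous variables are split at the
median by default (the source table mixes medians with other, underivable
cutoffs, which are not reproduced).

Degenerate inputs are errors, not silent results: empty classes or masks,
no events, collinear or constant covariates, no cases/controls at the
evaluation time, and empty Fisher margins (p = 1 with a warning, by
convention).

## Numerical choices

float32 network arithmetic with a float64 softmax (probability pairs sum
to 1 within 1e-9); Greenwood variance guarded at S = 0; PSI ε-guard
1e-12; batch-norm ε 1e-5, momentum 0.1; Adam (0.9, 0.999, 1e-8). All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state.

## Known limitations

- Single index lesion per patient; multifocal disease is an extension point.
- The PNU scorer is linear in the deep features; deep/nonlinear PNU heads
  and class-prior estimation are out of scope.
- Clinical AUC/sensitivity figures from any real cohort are not
  reproducible here by construction; the packaged experiments establish
  mechanism-level properties (WSDL ≥ CDL on average, oracle labels as an
  upper bound, calibrated type-I error) on synthetic data only.
- CPU-only training: the desk-scale configuration trades capacity for
  runtime, and larger configurations, while supported, train slowly.
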